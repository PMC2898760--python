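# tagdge — tag-based digital gene expression analysis

`tagdge` implements the classic SAGE-style **digital gene expression (DGE)**
analysis used to profile transcriptomes of non-model organisms (for example
a de-novo-assembled insect transcriptome across developmental stages) by
counting short 3'-anchored sequence tags rather than full-length reads.

The pipeline, end to end:

1. **Virtual tag reference** — every transcript is scanned for NlaIII sites
   (`CATG`); each site with ≥ 17 nt downstream yields a 21 nt *virtual tag*
   (`CATG` + 17 nt, the fragment MmeI releases), the 3'-most site is flagged
   *canonical*, and an inverted index tag → genes records ambiguity.
2. **Filtering** — raw reads are cleaned in a fixed, audited order:
   adaptor-only/anchorless reads, tags containing `N`, low-complexity tags,
   and (after aggregation) copy-number-1 tags, which are treated as probable
   sequencing errors.
3. **Mapping** — each distinct clean tag is matched to the reference
   allowing at most one substitution in the 17 variable nt (exact hits
   shadow 1-mismatch hits); tags hitting more than one gene are discarded as
   ambiguous, and a gene's expression is the sum of its unambiguous tag
   counts.
4. **Quantification** — counts are normalised to **TPM** (transcript copies
   per million clean tags): `tpm = count / N_clean × 10⁶`. Library
   evaluation includes tag-abundance distributions, sequencing-saturation
   curves, and between-library Pearson correlation over tag entities.
5. **Differential expression** — for a gene with counts *x* of *N₁* and *y*
   of *N₂* tags in two libraries, the Audic–Claverie conditional model

   P(y | x) = (N₂/N₁)ʸ (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) )

   gives an exact two-sided p-value (doubled smaller tail); q-values come
   from Benjamini–Hochberg, and a gene is called up-/down-regulated when
   FDR < 0.001 and |log₂(tpm₂/tpm₁)| ≥ 1, with a 0.001 TPM pseudo-value for
   genes seen in only one library.

A **ground-truthed simulator** (`tagdge.simulate`) generates transcriptomes,
per-stage abundances with planted fold changes, and tag libraries under an
explicit digestion / sequencing-error / contamination model, so every stage
of the pipeline can be validated against planted truth — including the
observation, familiar from real DGE libraries, that only ~60% of tags map to
the canonical site when digestion is incomplete.

## Worked example

```python
from tagdge import (SimulationConfig, simulate_experiment, build_reference,
                    filter_tags, quantify, call_de)

cfg = SimulationConfig(n_genes=500, library_size=100_000, seed=42)
exp = simulate_experiment(cfg, ("pupa", "adult"))
ref = build_reference(exp.transcripts)
genes = [t.gene_id for t in ref.transcripts]

tables = {}
for stage, raw in exp.libraries.items():
    lib = filter_tags(raw, cfg.adaptor_seq)
    tables[stage], summary = quantify(lib, ref, gene_ids=genes)
    print(stage, lib.n_clean_total, round(summary.canonical_fraction, 3))

table, de = call_de(tables["pupa"], tables["adult"])
print(de.n_up, de.n_down, "of", de.n_tested, "genes tested")
```

prints

```
pupa 96817 0.729
adult 96685 0.734
17 15 of 492 genes tested
```

i.e. ~96.7k of 100k raw tags survive cleaning in each library, ~73% of
mapped occurrences hit the canonical site (d = 0.6 plus single-site genes,
which can only produce canonical tags), and 32 genes change significantly
out of the 50 planted DE genes — the shortfall sits among low-abundance
genes, which lack power at this modest 100k-tag depth (the acceptance
script shows > 95% recovery at 2M tags).

The same steps are available from the shell:

```bash
tagdge simulate -o sim/ --conditions pupa,adult --seed 42
tagdge build-ref sim/transcriptome.fasta -o refdb/
tagdge filter sim/pupa.raw_tags.tsv --adaptor TCGTATGCCGTCTTCTGCTTG -o pupa.tags.tsv
tagdge run config.yaml      # full pipeline from a YAML config
```

## Analysis scripts

`analysis/01…05_*.py` form a narrative re-analysis of a synthetic
three-stage developmental series (egg & nymph → pupa → adult analogue,
2,000 genes, 500k tags/stage): simulation and planted truth, reference
census, library statistics, expression summaries, and pairwise differential
expression scored against the planted truth. Each writes its tables under
`results/analysis/`; bulky intermediates go to `scratch/`.

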