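# Methods

## The measurement model

Tag-based DGE profiles a transcriptome by sequencing 21 nt tags anchored at
NlaIII restriction sites: the enzyme recognises `CATG`, and MmeI cuts 17 bp
downstream, so a tag is `CATG` plus the next 17 nt of the transcript's
sense strand. Under complete digestion every transcript contributes tags
only from its 3'-most (`canonical`) site; incomplete digestion and
alternative 3' ends spread tags over upstream sites. Expression is measured
by absolute tag counts, which makes two-library comparisons a problem of
comparing two Poisson-like counts with known totals — the setting the
Audic–Claverie conditional test was designed for.

## Virtual tag reference

`tagdge.reference` scans the sense strand of every transcript for `CATG`
occurrences (overlaps included) and emits one virtual tag per site with at
least 17 nt downstream. Truncated tags are never emitted: a site closer
than 17 nt to the 3' end cannot produce the fragment MmeI releases, so
indexing a shorter tag would invite spurious matches. Tags containing `N`
are excluded — they can never match a clean sequenced tag exactly and only
inflate ambiguity classes. Coordinates are 0-based with `site_pos` at the C
of `CATG`; the tag is the half-open slice `[site_pos, site_pos+21)`.
Reverse-complement indexing (for de novo contigs of unknown orientation)
exists behind `both_strands` but is off by default, since an oriented
reference maps tags on the sense strand only.

All sites are indexed, not just canonical ones. This is what lets the
mapper *observe* the canonical-site fraction (~60% under incomplete
digestion) instead of silently discarding upstream-site tags;
canonical-only counting remains available by filtering on the per-tag flag.

## Filtering

Rules run in a fixed order so the audit is reproducible and conservation is
exact (reads in = reads kept + reads removed, rule by rule):

1. **adaptor_or_empty** — a read is trimmed of a leading adaptor if
   present and must then begin with a full `CATG`+17 tag. This bucket
   also collects real reads whose anchor was destroyed by a sequencing
   error, which is the physically correct outcome: such reads are
   indistinguishable from junk.
2. **contains_N** — undetermined bases.
3. **low_complexity** — the criterion is a config choice (the field never
   standardised one): a tag is rejected when a single nucleotide occupies
   ≥ 15 of the 17 variable positions or the 17-mer is a pure
   di-nucleotide repeat. This catches homopolymer and primer artifacts
   while leaving real tags (empirically zero false positives on simulated
   libraries) untouched.
4. **copy_number_1** — distinct tags seen once in the whole library,
   removed after aggregation. Rationale: at per-base error rate *e*, a
   deep library produces a long tail of singleton error tags; dropping
   singletons removes most of them at negligible cost to genuinely
   expressed tags (which almost surely recur at realistic depths).

Quality scores are not used beyond the `N` rule.

## Mapping

A clean tag is looked up exactly; failing that, all 51 one-substitution
variants of its 17 variable nt are looked up, and the gene set is the union
of hits at the minimal mismatch level (exact hits shadow 1-mismatch hits).
The mismatch budget excludes the anchor deliberately — for a CATG-anchored
reference an anchor mismatch can never match anything, so the restriction
is exhaustive, not an approximation; `variable_region_only=False` extends
enumeration to all 21 positions for non-anchored references. Output is
required to agree bit-for-bit with a brute-force Hamming scan, which the
test suite enforces on random queries.

Tags hitting multiple genes are ambiguous and excluded from counting; tags
hitting multiple sites of one gene count for that gene (gene-level
quantification), with the 3'-most hit site deciding canonicality. The
canonical fraction is reported over unambiguously mapped occurrences.

## Quantification and library evaluation

TPM is `count / N_clean × 10⁶` with the *clean* library total as
denominator (not the mapped total) — the classical definition; the switch
matters only for cross-package comparisons. Genes absent from a library
report 0 TPM, never missing; the 0 → 0.001 TPM pseudo-value exists only at
ratio time.

Abundance distributions use copy-number bins `[1], [2,5], [6,10], [11,20],
[21,50], [51,100], [101,500], [501,1000], >1000` (configurable); bins must
be disjoint, ordered and gap-free so both the distinct-entity and
occurrence totals are conserved partitions.

Saturation subsamples the occurrence multiset without replacement in a
single shuffled pass, so successive depths are nested and the
detected-gene curve is monotone by construction; the final point equals
full-library detection. Seeded, bit-reproducible.

Between-library correlation is Pearson's r over the union of tag entities
(absent = 0) on log10(count+1), with raw-scale r behind a flag. The
transform choice is consequential: raw-scale r is dominated by abundant
tags and sits near 1 for replicate draws (~0.9998 in simulation), matching
the 0.96–0.99 typically reported for parallel DGE libraries, while
log-scale r (~0.92 at defaults) is sensitive to the Poisson noise of
recurrent sequencing-error tags. Both are reported by the acceptance
script.

## Differential expression

For counts *x*/*N₁* and *y*/*N₂*, the conditional distribution of *y* given
*x* under a flat prior on the common rate is negative binomial with
*r = x+1* and success probability *N₁/(N₁+N₂)*. The implementation sums
tail terms of log P(y'|x) (log-gamma form) outward from the observation in
chunks, truncating once a chunk contributes less than 1e-16 of the
accumulated mass; the two-sided p doubles the smaller tail, capped at 1.
Accuracy is ~1e-13 relative against independent oracles (exact-rational
summation; scipy's negative-binomial tails).

Two numerical footnotes:

* **Sidedness** is a choice (the doubled smaller tail, two-sided by
  default; one-sided available). Nothing in the classical description of
  the test fixes it.
* **Exchange symmetry** holds exactly at the pmf level
  (N₂·P(y|x;N₁,N₂) = N₁·P(x|y;N₂,N₁)) but only approximately for tail-sum
  p-values: swapping the libraries changes which count is conditioned on,
  and the discrete tails can differ by up to a factor (N₁+N₂)/min(N₁,N₂)
  (e.g. x=2, y=0, N₂=2N₁: 0.074 vs 0.222). The tests assert the exact pmf
  identity and bound the p-value discrepancy rather than pretending the
  tail sums are symmetric.

FDR control is Benjamini–Hochberg step-up (delegated to statsmodels,
cross-checked against a hand-rolled oracle); a q-value-style procedure
would also fit but is not implemented. Calls require FDR < α (default
0.001) *and* |log₂ ratio| ≥ 1; published DGE tables sometimes print the
fold-change threshold as "log2Ratio ≤ 1", which contradicts their own
up/down usage — the absolute-value reading is implemented. The test uses
raw unambiguous counts with clean totals as N₁/N₂ (switchable to mapped
totals). Genes with zero counts in both libraries are excluded; genes seen
in one library only are tested normally and flagged `one_sample_only`.

A tag-level mode (`call_de_tag_level`: test each unambiguous tag entity,
then call a gene DE when at least one tag is significant and all its
significant tags agree in direction, `discordant` otherwise) mirrors
reports that count "significantly changed tag entities". Gene-level
testing is the default: it pools a gene's sites into one better-powered
count and avoids double-counting genes with many sites.

## The simulator

`tagdge.simulate` generates the conditions the analysis assumes:

* **Transcriptome** — i.i.d. uniform DNA; log-normal lengths (median
  300 nt, σ_log 0.35, floor 60 nt — the scale of short de novo assembled
  transcripts). `guarantee_catg` plants a `CATG` at length−21 (and further
  sites 25 nt apart for `min_usable_sites` ≥ 2) so every gene is taggable.
* **Abundances** — log-normal across genes (σ_log 1.5, spanning ~3 orders
  of magnitude); conditions chain, with round(de_fraction × eligible)
  genes per consecutive pair scaled by 2^±log2FC (sign random).
  Defaults: 10% DE at |log₂FC| = 2.
* **Libraries** — each read picks a gene ∝ abundance, then the canonical
  site with probability *d* (default 0.6, the digestion completeness
  behind the ~60% canonical mapping fraction) or a uniform upstream
  usable site. Genes with a single usable site can only emit canonical
  tags, so the observed canonical fraction exceeds *d* unless every gene
  has ≥ 2 sites — the parameter-recovery analyses therefore use
  `min_usable_sites=2`, where the binomial model for the canonical
  fraction is exact. Each base substitutes independently with probability
  *e* = 0.001 (uniform over alternatives; substitutions only, since
  fixed-length tags admit no indels); `N`-corrupted tags (1%) and
  adaptor-only reads (0.5%) are injected, with `N`s confined to the
  variable region so the filter audit remains attributable to planted
  classes. All randomness flows from one seed through SeedSequence
  spawning; outputs are byte-reproducible.

What the simulator does **not** model: quality-score profiles, correlated
(technical-replicate) noise between libraries, alternative polyadenylation
or splicing isoforms (a real secondary source of non-canonical tags), and
assembly redundancy (near-duplicate contigs creating ambiguous tags).
Passing tests therefore demonstrate correctness of the pipeline's
*computations* under its stated model, not robustness to those real-data
features.

## Problem sizes

Simulation-based checks run at 2,000 genes with 0.5–2M tags per library
(the depth regime of real DGE libraries, with the gene count scaled to
desk size): type-I calibration on a fully null pair at 1M tags, planted-DE
recovery at 2M tags (sensitivity ≥ 0.90 is met with ~0.97 observed;
frozen seeded rates are asserted exactly as regression values), canonical
fraction at 500k tags (±0.01), and the oracle grid at x, y ≤ 200 with
library ratios 0.5/1/2. The analysis scripts use 500k-tag libraries,
where DE sensitivity is ~0.84 — the expected power cost of shallower
sequencing, not an implementation difference.

## Known limitations

* One library per condition: no dispersion estimation, no replicates —
  the exact test treats all variation as counting noise, so biological
  variability inflates significance in real designs.
* Ambiguous tags are discarded, not redistributed (no EM rescue).
* The low-complexity criterion and adaptor handling are necessarily
  config choices; published pipelines did not specify them.
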