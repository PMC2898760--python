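"""Expression-level summaries: distributions, saturation, correlation,
stage profiles.

Quantifies each stage library in TPM, bins tag and gene abundances (the
deep-library contrast: occurrences concentrate in high-copy tags while most
distinct tags are low-copy), runs the sequencing-saturation analysis, and
computes between-stage Pearson correlations over tag entities.  Also pulls
stage profiles for the most stage-specific genes, the analogue of marker
genes in a developmental series.
"""

import itertools
import json

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS, SEED, STAGES, load_experiment
from tagdge.expression import (
    DEFAULT_BINS,
    abundance_distribution,
    library_correlation,
    quantify,
    saturation,
)
from tagdge.filtering import filter_tags
from tagdge.pipeline import profile_genes
from tagdge.reference import build_reference


def main() -> None:
    exp = load_experiment()
    ref = build_reference(exp.transcripts)
    genes = [t.gene_id for t in ref.transcripts]

    clean, tables = {}, {}
    for stage in STAGES:
        clean[stage] = filter_tags(exp.libraries[stage], CONFIG.adaptor_seq)
        tables[stage], _ = quantify(clean[stage], ref, gene_ids=genes)

    expr = pd.concat({s: t.to_frame() for s, t in tables.items()}, axis=1)
    expr.to_csv(RESULTS / "04_expression.tsv", sep="\t")

    dists = []
    for stage in STAGES:
        d = abundance_distribution(clean[stage].counts, DEFAULT_BINS)
        d.insert(0, "stage", stage)
        dists.append(d)
    dist = pd.concat(dists, ignore_index=True)
    dist.to_csv(RESULTS / "04_tag_abundance_distribution.tsv", sep="\t", index=False)

    curves = []
    for stage in STAGES:
        c = saturation(clean[stage], ref, step=25_000, seed=SEED)
        c.insert(0, "stage", stage)
        curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(
        RESULTS / "04_saturation.tsv", sep="\t", index=False
    )

    corr = {
        f"{a}:{b}": round(library_correlation(clean[a], clean[b]), 4)
        for a, b in itertools.combinations(STAGES, 2)
    }
    with open(RESULTS / "04_correlations.json", "w") as fh:
        json.dump(corr, fh, indent=2)

    # stage-specific markers: largest adult/egg_nymph TPM contrast
    tpm = expr.xs("tpm", axis=1, level=1)
    lr = np.log2((tpm[STAGES[-1]] + 1) / (tpm[STAGES[0]] + 1))
    markers = list(lr.nlargest(3).index) + list(lr.nsmallest(3).index)
    prof, _ = profile_genes(markers, tables)
    prof.round(1).to_csv(RESULTS / "04_marker_profiles.tsv", sep="\t")

    print("Tag-abundance distribution (per stage):")
    print(dist.to_string(index=False))
    print("\nBetween-stage Pearson correlations (log10(count+1), tag union):")
    print(json.dumps(corr, indent=2))
    sat_last = {s: int(c.n_detected_genes.iloc[-1]) for s, c in zip(STAGES, curves)}
    print("\nDetected genes at full depth:", sat_last)
    print("\nStage profiles of the most stage-contrasted genes (TPM):")
    print(prof.round(1).to_string())


if __name__ == "__main__":
    main()
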