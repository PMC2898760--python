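"""Build the virtual CATG+17 tag reference and report its census.

Extracts every usable NlaIII tag from the synthetic transcriptome, flags
canonical (3'-most) sites, and reports the reference-tag census: how many
distinct tags exist, how many identify a single gene unambiguously, and how
many genes are taggable at all.
"""

import json

import pandas as pd

from common import RESULTS, load_experiment
from tagdge.reference import build_reference


def main() -> None:
    exp = load_experiment()
    ref = build_reference(exp.transcripts)
    census = ref.census()
    with open(RESULTS / "02_reference_census.json", "w") as fh:
        json.dump(census, fh, indent=2)

    sites_per_gene = (
        pd.Series([v.gene_id for v in ref.virtual_tags])
        .value_counts()
        .reindex([t.gene_id for t in ref.transcripts], fill_value=0)
    )
    dist = sites_per_gene.value_counts().sort_index().rename_axis(
        "n_usable_sites"
    ).rename("n_genes")
    dist.to_csv(RESULTS / "02_sites_per_gene.tsv", sep="\t")

    print("Reference census:")
    for k, v in census.items():
        print(f"  {k}: {v}")
    print("\nUsable CATG sites per gene:")
    print(dist.to_string())
    ambiguous = census["n_distinct_tags"] - census["n_unambiguous_ref_tags"]
    print(f"\n{ambiguous} distinct tags are shared by more than one gene "
          "and can never be used for quantification.")


if __name__ == "__main__":
    main()
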