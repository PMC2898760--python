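"""Tag-to-gene mapping with a one-mismatch budget.

A clean tag is mapped to the virtual-tag reference allowing at most one
nucleotide substitution.  Exact hits shadow one-mismatch hits: the gene set
of a hit is the union of genes matched at the *minimal* mismatch level only.
Tags whose gene set contains more than one gene are ambiguous and contribute
nothing to quantification; tags hitting several sites of a single gene stay
unambiguous (gene-level counting), with the 3'-most hit site deciding
canonicality.

The mismatch lives in the 17 variable positions: for a CATG-anchored
reference an anchor mismatch can never match anyway (every reference tag and
every clean query begins CATG), so enumerating the 51 variants
(3 alternatives x 17 positions) is exhaustive.  ``variable_region_only=False``
extends enumeration to all 21 positions, which only matters for references
that are not CATG-anchored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .filtering import TagLibrary
from .reference import ANCHOR, TAG_LEN, TagReference, VirtualTag

_BASES = "ACGT"


class MalformedTagError(ValueError):
    """Query tag is not a clean 21 nt CATG-anchored ACGT string."""


@dataclass(frozen=True)
class TagHit:
    tag_seq: str
    gene_ids: frozenset[str]
    n_mismatches: int
    #: canonicality of the 3'-most hit site; meaningful only when the hit is
    #: unambiguous (|gene_ids| == 1)
    site_is_canonical: bool | None = None


@dataclass
class MappingSummary:
    """Library-level mapping statistics (the per-library report row).

    Percentages are against the clean totals and the reference gene count;
    ``canonical_fraction`` is the share of unambiguously mapped tag
    occurrences whose hit site is the canonical (3'-most) one.
    """

    n_clean_total: int
    n_clean_distinct: int
    n_total_tags_mapped: int
    n_distinct_tags_mapped: int
    n_total_unambiguous: int
    n_distinct_unambiguous: int
    n_tag_mapped_genes: int
    n_ref_genes: int
    canonical_fraction: float

    @property
    def pct_total_mapped(self) -> float:
        return 100.0 * self.n_total_tags_mapped / self.n_clean_total if self.n_clean_total else 0.0

    @property
    def pct_distinct_mapped(self) -> float:
        return 100.0 * self.n_distinct_tags_mapped / self.n_clean_distinct if self.n_clean_distinct else 0.0

    @property
    def pct_genes_mapped(self) -> float:
        return 100.0 * self.n_tag_mapped_genes / self.n_ref_genes if self.n_ref_genes else 0.0

    def as_dict(self) -> dict:
        return {
            "n_clean_total": self.n_clean_total,
            "n_clean_distinct": self.n_clean_distinct,
            "n_total_tags_mapped": self.n_total_tags_mapped,
            "pct_total_mapped": self.pct_total_mapped,
            "n_distinct_tags_mapped": self.n_distinct_tags_mapped,
            "pct_distinct_mapped": self.pct_distinct_mapped,
            "n_total_unambiguous": self.n_total_unambiguous,
            "n_distinct_unambiguous": self.n_distinct_unambiguous,
            "n_tag_mapped_genes": self.n_tag_mapped_genes,
            "n_ref_genes": self.n_ref_genes,
            "pct_genes_mapped": self.pct_genes_mapped,
            "canonical_fraction": self.canonical_fraction,
        }


def _validate_query(tag_seq: str) -> None:
    if (
        len(tag_seq) != TAG_LEN
        or not tag_seq.startswith(ANCHOR)
        or set(tag_seq) - set(_BASES)
    ):
        raise MalformedTagError(
            f"query must be a {TAG_LEN} nt ACGT string starting with {ANCHOR}: {tag_seq!r}"
        )


def _one_sub_variants(tag_seq: str, start: int) -> Iterable[str]:
    for i in range(start, TAG_LEN):
        orig = tag_seq[i]
        for b in _BASES:
            if b != orig:
                yield tag_seq[:i] + b + tag_seq[i + 1:]


def _resolve(tag_seq: str, hits: list[VirtualTag], n_mismatches: int) -> TagHit:
    genes = frozenset(vt.gene_id for vt in hits)
    canonical = None
    if len(genes) == 1:
        best = max(hits, key=lambda v: v.site_pos)  # 3'-most hit site
        canonical = best.is_canonical
    return TagHit(tag_seq=tag_seq, gene_ids=genes, n_mismatches=n_mismatches,
                  site_is_canonical=canonical)


def map_tag(
    tag_seq: str, ref: TagReference, *, variable_region_only: bool = True
) -> TagHit | None:
    """Map one clean tag; returns None when nothing matches within one
    substitution.  Deterministic regardless of index iteration order."""
    _validate_query(tag_seq)
    exact = ref.index.get(tag_seq)
    if exact:
        return _resolve(tag_seq, list(exact), 0)
    start = len(ANCHOR) if variable_region_only else 0
    hits: list[VirtualTag] = []
    for variant in _one_sub_variants(tag_seq, start):
        hits.extend(ref.index.get(variant, ()))
    if not hits:
        return None
    return _resolve(tag_seq, hits, 1)


def count_unambiguous(
    lib: TagLibrary, ref: TagReference, *, variable_region_only: bool = True
) -> tuple[pd.Series, MappingSummary]:
    """Per-gene unambiguous tag counts plus the mapping summary.

    Only hits confined to a single gene contribute; a gene's count is the sum
    of the library counts of its unambiguous tags.  The summary's "mapped"
    numbers count any hit (ambiguous included) so that
    mapped + unmapped == clean total exactly.
    """
    counts: dict[str, int] = {}
    n_total_mapped = n_distinct_mapped = 0
    n_total_unamb = n_distinct_unamb = 0
    n_canonical_occ = 0
    for tag in sorted(lib.counts):
        n = lib.counts[tag]
        hit = map_tag(tag, ref, variable_region_only=variable_region_only)
        if hit is None:
            continue
        n_total_mapped += n
        n_distinct_mapped += 1
        if len(hit.gene_ids) == 1:
            (gene,) = hit.gene_ids
            counts[gene] = counts.get(gene, 0) + n
            n_total_unamb += n
            n_distinct_unamb += 1
            if hit.site_is_canonical:
                n_canonical_occ += n
    summary = MappingSummary(
        n_clean_total=lib.n_clean_total,
        n_clean_distinct=lib.n_clean_distinct,
        n_total_tags_mapped=n_total_mapped,
        n_distinct_tags_mapped=n_distinct_mapped,
        n_total_unambiguous=n_total_unamb,
        n_distinct_unambiguous=n_distinct_unamb,
        n_tag_mapped_genes=len(counts),
        n_ref_genes=ref.n_genes,
        canonical_fraction=(n_canonical_occ / n_total_unamb) if n_total_unamb else 0.0,
    )
    return pd.Series(counts, dtype="int64").sort_index(), summary


def tag_gene_assignments(
    lib: TagLibrary, ref: TagReference, *, variable_region_only: bool = True
) -> pd.DataFrame:
    """Per distinct tag: count, mapped gene (if unambiguous), mismatch level.

    Columns: tag_seq, count, gene_id (empty for unmapped/ambiguous),
    n_genes, n_mismatches (-1 for unmapped), site_is_canonical.
    """
    rows = []
    for tag in sorted(lib.counts):
        hit = map_tag(tag, ref, variable_region_only=variable_region_only)
        if hit is None:
            rows.append((tag, lib.counts[tag], "", 0, -1, False))
        else:
            gene = next(iter(hit.gene_ids)) if len(hit.gene_ids) == 1 else ""
            rows.append((tag, lib.counts[tag], gene, len(hit.gene_ids),
                         hit.n_mismatches, bool(hit.site_is_canonical)))
    return pd.DataFrame(
        rows,
        columns=["tag_seq", "count", "gene_id", "n_genes", "n_mismatches",
                 "site_is_canonical"],
    )


def write_counts(counts: pd.Series, path: str | Path) -> None:
    counts.rename_axis("gene_id").rename("raw_count").to_csv(path, sep="\t")


def write_summary(summary: MappingSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")
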