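"""Expression quantification and library evaluation.

Expression is measured in TPM — transcript copies per million tags: a gene's
unambiguous tag count divided by the library's *clean* tag total, times 1e6.
The module also provides the standard library-evaluation summaries for a
tag-profiling experiment: tag-abundance / gene-expression distributions over
copy-number bins, sequencing-saturation curves (detected genes vs subsampled
depth), and between-library Pearson correlation over tag entities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import TagLibrary
from .mapping import count_unambiguous
from .reference import TagReference

#: default copy-number bins: [1], [2,5], ..., >1000 (upper bound None = open)
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 1), (2, 5), (6, 10), (11, 20), (21, 50), (51, 100),
    (101, 500), (501, 1000), (1001, None),
)


class ZeroLibraryTotalError(ValueError):
    """TPM normalization requires a positive clean library total."""


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined when one library has no variance."""


class InvalidBinsError(ValueError):
    """Bins must be disjoint, ordered and cover [1, inf)."""


@dataclass
class ExpressionTable:
    """Per-gene raw unambiguous counts and TPM for one library."""

    sample_id: str
    counts: pd.Series  # gene_id -> raw unambiguous tag count
    tpm: pd.Series  # gene_id -> transcripts per million tags
    library_total: int  # clean tag total used as the TPM denominator

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"raw_count": self.counts, "tpm": self.tpm}).rename_axis(
            "gene_id"
        )


def to_tpm(
    counts: Mapping[str, int] | pd.Series,
    library_total: int,
    *,
    sample_id: str = "",
    gene_ids: Sequence[str] | None = None,
) -> ExpressionTable:
    """Normalize raw per-gene counts to TPM.

    ``gene_ids`` optionally fixes the full gene universe; genes without
    counts get 0 TPM (the 0 -> 0.001 pseudo-value is applied only when
    forming expression ratios, never here).
    """
    if library_total <= 0:
        raise ZeroLibraryTotalError("library_total must be a positive tag count")
    counts = pd.Series(counts, dtype="int64")
    if gene_ids is not None:
        counts = counts.reindex(gene_ids, fill_value=0)
    counts = counts.sort_index()
    tpm = counts * (1e6 / library_total)
    return ExpressionTable(
        sample_id=sample_id, counts=counts, tpm=tpm, library_total=library_total
    )


def _validate_bins(bins: Sequence[tuple[int, int | None]]) -> None:
    if not bins or bins[0][0] != 1 or bins[-1][1] is not None:
        raise InvalidBinsError("bins must start at 1 and end with an open interval")
    for (lo, hi), (nlo, _) in zip(bins, bins[1:]):
        if hi is None or hi < lo or nlo != hi + 1:
            raise InvalidBinsError(f"bins must be ordered, disjoint and gap-free: {bins}")


def abundance_distribution(
    values: Mapping[str, float] | pd.Series,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Bin entities (tags or genes) by copy number / TPM.

    Returns one row per bin with ``n_distinct`` (entities in the bin) and
    ``n_total`` (their summed values); every entity falls in exactly one bin
    so both columns are conserved under any valid binning.
    """
    _validate_bins(list(bins))
    vals = pd.Series(values, dtype="float64")
    vals = vals[vals >= 1]
    rows = []
    for lo, hi in bins:
        mask = (vals >= lo) if hi is None else (vals >= lo) & (vals <= hi)
        label = f"[{lo},{hi}]" if hi is not None else f">{lo - 1}"
        if lo == hi:
            label = f"[{lo}]"
        rows.append((label, int(mask.sum()), float(vals[mask].sum())))
    return pd.DataFrame(rows, columns=["bin", "n_distinct", "n_total"])


def saturation(
    lib: TagLibrary,
    ref: TagReference,
    step: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Detected-gene count as a function of subsampled sequencing depth.

    Tag occurrences are subsampled without replacement at cumulative sizes
    step, 2*step, ... (single shuffled pass, so the subsamples are nested and
    the curve is monotone by construction); at each depth a gene counts as
    detected if at least one of its unambiguously mapped tags is present.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tags = sorted(lib.counts)
    # gene index per distinct tag; -1 = unmapped or ambiguous
    gene_of_tag = np.full(len(tags), -1, dtype=np.int64)
    gene_index: dict[str, int] = {}
    from .mapping import map_tag  # local import to keep module deps one-way

    for i, t in enumerate(tags):
        hit = map_tag(t, ref)
        if hit is not None and len(hit.gene_ids) == 1:
            (g,) = hit.gene_ids
            gene_of_tag[i] = gene_index.setdefault(g, len(gene_index))

    occ = np.repeat(np.arange(len(tags)), [lib.counts[t] for t in tags])
    rng.shuffle(occ)
    n = len(occ)
    checkpoints = list(range(step, n, step)) + [n]
    seen = np.zeros(len(gene_index), dtype=bool)
    rows, prev = [], 0
    for c in checkpoints:
        genes = gene_of_tag[occ[prev:c]]
        seen[genes[genes >= 0]] = True
        rows.append((c, int(seen.sum())))
        prev = c
    return pd.DataFrame(rows, columns=["n_subsampled_tags", "n_detected_genes"])


def library_correlation(
    a: TagLibrary, b: TagLibrary, *, log_transform: bool = True
) -> float:
    """Pearson r between two libraries over the union of their tag entities
    (absent tag = count 0), on log10(count+1) by default."""
    if not a.counts or not b.counts:
        raise ValueError("both libraries must be nonempty")
    union = sorted(set(a.counts) | set(b.counts))
    va = np.array([a.counts.get(t, 0) for t in union], dtype=float)
    vb = np.array([b.counts.get(t, 0) for t in union], dtype=float)
    if log_transform:
        va, vb = np.log10(va + 1), np.log10(vb + 1)
    if va.std() == 0 or vb.std() == 0:
        raise ZeroVarianceError("a library has zero variance across the tag union")
    return float(stats.pearsonr(va, vb).statistic)


def quantify(
    lib: TagLibrary, ref: TagReference, *, gene_ids: Sequence[str] | None = None
):
    """Map, count and normalize one clean library in a single call.

    Returns (ExpressionTable, MappingSummary).  The TPM denominator is the
    clean library total, not the mapped total.
    """
    counts, summary = count_unambiguous(lib, ref)
    if gene_ids is None:
        gene_ids = [t.gene_id for t in ref.transcripts]
    table = to_tpm(
        counts, lib.n_clean_total, sample_id=lib.sample_id, gene_ids=gene_ids
    )
    return table, summary
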