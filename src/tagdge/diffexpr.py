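"""Differential expression between two tag libraries.

With a single library per condition, the natural test for "is this gene's
tag frequency different between library 1 (x of N1 tags) and library 2
(y of N2 tags)?" is the Audic-Claverie exact statistic: under a flat prior
on the unknown common rate, the conditional distribution of the second count
given the first is

    P(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

i.e. y | x is negative-binomial with r = x+1 successes and success
probability N1/(N1+N2).  The two-sided p-value doubles the smaller tail
(lower: y' <= y, upper: y' >= y), capped at 1.

Everything is computed in the log domain via log-gamma; tails are summed
outward from the observation in chunks and truncated once a chunk adds less
than 1e-16 of the accumulated mass, giving ~1e-12 relative accuracy.

Significance calls follow the standard tag-DGE convention: a gene is up- or
down-regulated when its Benjamini-Hochberg FDR is below alpha (default
0.001) and |log2 TPM ratio| >= 1, with a 0.001 TPM pseudo-value replacing
zeros when forming the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionTable

#: TPM pseudo-value substituted for 0 when forming log2 ratios
TPM_PSEUDO = 0.001
#: relative truncation threshold for tail summation
_TAIL_RTOL = 1e-16
_CHUNK = 512


class InvalidCountsError(ValueError):
    """Counts/totals violate the test's preconditions."""


class MismatchedTablesError(ValueError):
    """The two expression tables were not built against the same genes."""


def _log_pmf(ys: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    # log P(y|x) = y log r + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1) - (x+y+1) log(1+r)
    return (
        ys * log_r
        + gammaln(x + ys + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ys + 1.0)
        - (x + ys + 1.0) * log_1pr
    )


def _log_tail(x: int, y: int, log_r: float, log_1pr: float, direction: int) -> float:
    """log of sum_{y' in tail} P(y'|x), summed outward from y (direction -1:
    lower tail down to 0; +1: upper tail upward, truncated)."""
    acc = -np.inf
    lo = y
    while True:
        if direction < 0:
            ys = np.arange(max(0, lo - _CHUNK + 1), lo + 1, dtype=float)
        else:
            ys = np.arange(lo, lo + _CHUNK, dtype=float)
        chunk = logsumexp(_log_pmf(ys, x, log_r, log_1pr))
        new = np.logaddexp(acc, chunk)
        done = False
        if direction < 0 and ys[0] == 0:
            done = True
        elif chunk < new + math.log(_TAIL_RTOL):
            done = True
        acc = new
        if done:
            return float(acc)
        lo = lo - _CHUNK if direction < 0 else lo + _CHUNK


def ac_log_pmf(x: int, y: int, n1: int, n2: int) -> float:
    """log P(y | x) under the conditional count model.

    The model's exchange symmetry lives here:
    N2 * P(y|x; N1,N2) == N1 * P(x|y; N2,N1).  The two-sided p-value built
    from tail sums inherits it only approximately, because the conditional
    tails are discrete.
    """
    if n1 <= 0 or n2 <= 0:
        raise InvalidCountsError("library totals N1, N2 must be positive")
    r = n2 / n1
    return float(_log_pmf(np.array([y], dtype=float), x, math.log(r), math.log1p(r))[0])


def ac_pvalue(
    x: int, y: int, n1: int, n2: int, *, alternative: str = "two-sided"
) -> float:
    """Audic-Claverie exact p-value for counts x/N1 vs y/N2.

    ``alternative``: "two-sided" (double the smaller tail, capped at 1),
    "greater" (P(y' >= y | x)), or "less" (P(y' <= y | x)).  Symmetric:
    ac_pvalue(x, y, N1, N2) == ac_pvalue(y, x, N2, N1).
    """
    if n1 <= 0 or n2 <= 0:
        raise InvalidCountsError("library totals N1, N2 must be positive")
    if x < 0 or y < 0:
        raise InvalidCountsError("counts must be nonnegative")
    r = n2 / n1
    log_r, log_1pr = math.log(r), math.log1p(r)
    lower = _log_tail(x, y, log_r, log_1pr, -1)
    upper = _log_tail(x, y, log_r, log_1pr, +1)
    if alternative == "less":
        return min(1.0, math.exp(lower))
    if alternative == "greater":
        return min(1.0, math.exp(upper))
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, 2.0 * math.exp(min(lower, upper)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, q_(i) = min_{j>=i} m p_(j) / j,
    returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(tpm1: float, tpm2: float) -> float:
    """log2(tpm2 / tpm1) with the 0 -> 0.001 TPM pseudo-value."""
    return math.log2(max(tpm2, TPM_PSEUDO) / max(tpm1, TPM_PSEUDO))


@dataclass
class DESummary:
    n_tested: int
    n_up: int
    n_down: int
    alpha: float
    min_abs_log2: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def call_de(
    table1: ExpressionTable,
    table2: ExpressionTable,
    *,
    alpha: float = 0.001,
    min_abs_log2: float = 1.0,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, DESummary]:
    """Per-gene differential-expression calls between two libraries.

    Each gene contributes its unambiguous counts (x, y) with the clean
    library totals as N1, N2; genes with zero counts in both libraries are
    excluded.  Returns a DataFrame (gene_id, count1, count2, tpm1, tpm2,
    log2_ratio, p_value, fdr, call, one_sample_only) sorted by gene_id, plus
    the up/down tally.  call is "up" iff fdr < alpha and log2_ratio >=
    min_abs_log2 (expression higher in library 2), "down" symmetrically,
    else "ns".
    """
    if not table1.counts.index.equals(table2.counts.index):
        raise MismatchedTablesError(
            "expression tables cover different gene sets; build both with "
            "the same reference"
        )
    n1, n2 = table1.library_total, table2.library_total
    df = pd.DataFrame(
        {
            "count1": table1.counts,
            "count2": table2.counts,
            "tpm1": table1.tpm,
            "tpm2": table2.tpm,
        }
    ).rename_axis("gene_id")
    df = df[(df.count1 > 0) | (df.count2 > 0)].sort_index()
    df["log2_ratio"] = [
        log2_ratio(t1, t2) for t1, t2 in zip(df.tpm1, df.tpm2)
    ]
    df["p_value"] = [
        ac_pvalue(int(x), int(y), n1, n2, alternative=alternative)
        for x, y in zip(df.count1, df.count2)
    ]
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    sig = df["fdr"] < alpha
    df["call"] = "ns"
    df.loc[sig & (df.log2_ratio >= min_abs_log2), "call"] = "up"
    df.loc[sig & (df.log2_ratio <= -min_abs_log2), "call"] = "down"
    df["one_sample_only"] = (df.count1 == 0) | (df.count2 == 0)
    summary = DESummary(
        n_tested=len(df),
        n_up=int((df.call == "up").sum()),
        n_down=int((df.call == "down").sum()),
        alpha=alpha,
        min_abs_log2=min_abs_log2,
    )
    return df.reset_index(), summary


def call_de_tag_level(
    lib1,
    lib2,
    ref,
    *,
    alpha: float = 0.001,
    min_abs_log2: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag-entity-level differential expression, collapsed to genes.

    The alternative route used in tag-DGE reports that count "significantly
    changed tag entities": every unambiguously mapped distinct tag is tested
    on its own counts (union of both libraries' tags; absent = 0), then a
    gene is called DE when at least one of its tags is significant and all
    its significant tags agree in direction.

    Returns (per-tag table, per-gene table).  ``lib1``/``lib2`` are clean
    TagLibrary objects and ``ref`` the TagReference both map against.
    """
    from .mapping import map_tag  # late import: avoids a module cycle

    n1 = lib1.n_clean_total
    n2 = lib2.n_clean_total
    rows = []
    for tag in sorted(set(lib1.counts) | set(lib2.counts)):
        hit = map_tag(tag, ref)
        if hit is None or len(hit.gene_ids) != 1:
            continue
        (gene,) = hit.gene_ids
        x = lib1.counts.get(tag, 0)
        y = lib2.counts.get(tag, 0)
        tpm1, tpm2 = x / n1 * 1e6, y / n2 * 1e6
        rows.append((tag, gene, x, y, log2_ratio(tpm1, tpm2),
                     ac_pvalue(x, y, n1, n2)))
    tags = pd.DataFrame(
        rows, columns=["tag_seq", "gene_id", "count1", "count2",
                       "log2_ratio", "p_value"]
    )
    if tags.empty:
        return tags.assign(fdr=[], call=[]), pd.DataFrame(
            columns=["gene_id", "n_sig_tags", "call"]
        )
    tags["fdr"] = bh_fdr(tags["p_value"].to_numpy())
    sig = tags.fdr < alpha
    tags["call"] = "ns"
    tags.loc[sig & (tags.log2_ratio >= min_abs_log2), "call"] = "up"
    tags.loc[sig & (tags.log2_ratio <= -min_abs_log2), "call"] = "down"

    gene_rows = []
    for gene, grp in tags.groupby("gene_id", sort=True):
        calls = set(grp.call) - {"ns"}
        if not calls:
            call = "ns"
        elif len(calls) == 1:
            call = calls.pop()
        else:
            call = "discordant"
        gene_rows.append((gene, int((grp.call != "ns").sum()), call))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "n_sig_tags", "call"])
    return tags, genes
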