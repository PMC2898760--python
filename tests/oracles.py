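"""Independent oracles used by the test suite.

Each oracle re-derives the expected behaviour by brute force or exact
arithmetic, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

TAG_LEN = 21


def naive_extract(seq: str) -> list[tuple[int, str, bool]]:
    """Brute-force virtual-tag scan: test every length-4 window for CATG and
    slice 21 nt.  Returns (site_pos, tag_seq, is_canonical) tuples."""
    hits = []
    for i in range(len(seq) - 3):
        if seq[i : i + 4] == "CATG" and i + TAG_LEN <= len(seq):
            tag = seq[i : i + TAG_LEN]
            if "N" not in tag:
                hits.append((i, tag))
    last = hits[-1][0] if hits else None
    return [(pos, tag, pos == last) for pos, tag in hits]


def naive_map(query: str, ref_tags: list[tuple[str, str]], *,
              variable_start: int = 4) -> tuple[frozenset[str], int] | None:
    """Brute-force Hamming scan over every reference tag.

    ``ref_tags`` is a list of (tag_seq, gene_id).  Mismatches at positions
    before ``variable_start`` disqualify a 1-mismatch hit (anchor must match
    exactly).  Returns (gene set at minimal distance, distance) or None.
    """
    best_d, genes = 2, set()
    for tag, gene in ref_tags:
        d = sum(a != b for a, b in zip(query, tag))
        if d == 1 and any(
            a != b for a, b in zip(query[:variable_start], tag[:variable_start])
        ):
            continue
        if d < best_d:
            best_d, genes = d, {gene}
        elif d == best_d:
            genes.add(gene)
    if best_d > 1:
        return None
    return frozenset(genes), best_d


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> float:
    """Exact-rational two-sided p-value: term-by-term summation of
    P(y'|x) = r^y' (x+y')! / (x! y'! (1+r)^(x+y'+1)) with r = N2/N1, in
    fractions.Fraction.  The upper tail uses the exact complement identity
    sum_{y'>=0} P(y'|x) == 1."""
    r = Fraction(n2, n1)

    def pmf(yy: int) -> Fraction:
        num = r**yy
        binom = Fraction(1)
        for k in range(1, yy + 1):
            binom *= Fraction(x + k, k)
        return num * binom / (1 + r) ** (x + yy + 1)

    lower = sum((pmf(t) for t in range(y + 1)), Fraction(0))
    upper = 1 - lower + pmf(y)
    p = 2 * min(lower, upper)
    return float(min(Fraction(1), p))


def ac_pvalue_longdouble_grid(x: int, n1: int, n2: int, y_max: int) -> np.ndarray:
    """Extended-precision (80-bit longdouble) term-by-term oracle.

    Returns two-sided p-values for y = 0..y_max at fixed x, computed from a
    multiplicative pmf recurrence with forward cumulative sums for lower
    tails and reverse (ascending-magnitude) sums for upper tails; the series
    is extended until terms underflow longdouble.
    """
    r = np.longdouble(n2) / np.longdouble(n1)
    q = r / (1 + r)
    # extend far enough that the dropped mass is negligible at longdouble scale
    n_terms = y_max + int(5000 / -np.log10(float(q))) + 200
    terms = np.empty(n_terms, dtype=np.longdouble)
    terms[0] = (1 / (1 + r)) ** np.longdouble(x + 1)
    ks = np.arange(1, n_terms, dtype=np.longdouble)
    ratios = q * (x + ks) / ks
    np.multiply.accumulate(ratios, out=ratios)
    terms[1:] = terms[0] * ratios
    lower = np.cumsum(terms)
    upper = np.cumsum(terms[::-1])[::-1]
    p = 2 * np.minimum(lower, upper)[: y_max + 1]
    return np.minimum(np.longdouble(1), p).astype(float)


def bh_stepup(pvalues) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up q-values, q_(i) = min_{j>=i}
    m p_(j) / j, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
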