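"""Shared statistical primitives.

Quantiles, Benjamini-Hochberg adjustment, and the Wilcoxon rank-sum
routine (exact or tie-corrected normal approximation, with the
Hodges-Lehmann location estimate) that several modules rely on.
The quantile and Wilcoxon conventions are isolated here so they are
testable and swappable in one place.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "quantile",
    "iqr",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "hodges_lehmann",
    "rank_sum_p_exact_table",
    "rank_sum_p_normal",
]


def quantile(a, q):
    """Interpolated quantile (linear between order statistics, R type 7)."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("quantile of empty data")
    return float(np.quantile(a, q))


def iqr(a) -> float:
    """Interquartile range Q3 - Q1 under the linear-interpolation convention."""
    a = np.asarray(a, dtype=float)
    return quantile(a, 0.75) - quantile(a, 0.25)


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def hodges_lehmann(x, y) -> float:
    """Median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(np.subtract.outer(x, y)))


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum test of x (altered) vs y (wildtype).

    Exact enumeration when both groups have <= 12 observations and the
    pooled data contain no ties; otherwise a normal approximation with
    tie and continuity correction.  Returns (p, estimate) where the
    estimate is the Hodges-Lehmann median of pairwise differences x - y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size <= 12 and y.size <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue), hodges_lehmann(x, y)


def rank_sum_p_exact_table(m: int, n: int):
    """Exact two-sided p for every possible Mann-Whitney U of group sizes m, n.

    Returns an array p[u] for u = 0..m*n (valid only when there are no
    ties).  Two-sided p doubles the smaller tail, capped at 1 — the
    convention of the exact rank-sum test.
    """
    pmf = _mwu_counts(m, n)
    pmf = pmf / pmf.sum()
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(U >= u)
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _mwu_counts(m: int, n: int):
    """Counts of rank assignments achieving each Mann-Whitney U.

    Recurrence N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1).
    """
    prev = [np.zeros(m * n + 1) for _ in range(n + 1)]
    for j in range(n + 1):
        prev[j][0] = 1.0  # m = 0
    for i in range(1, m + 1):
        cur = [np.zeros(m * n + 1) for _ in range(n + 1)]
        cur[0][0] = 1.0
        for j in range(1, n + 1):
            cur[j] = cur[j - 1].copy()
            cur[j][j:] += prev[j][: m * n + 1 - j]
        prev = cur
    return prev[n]


def rank_sum_p_normal(u, m, n, tie_term=0.0):
    """Vectorized two-sided normal-approximation p with tie/continuity correction.

    ``u`` is the Mann-Whitney U of the first group; ``tie_term`` is
    sum(t^3 - t) over tie groups of the pooled sample.  Matches the
    formula used by the scalar routine's asymptotic branch.
    """
    u = np.asarray(u, dtype=float)
    N = m + n
    mu = m * n / 2.0
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    if var <= 0:
        return np.ones_like(u)
    num = np.abs(u - mu) - 0.5
    num = np.maximum(num, 0.0)
    z = num / np.sqrt(var)
    return np.minimum(1.0, 2.0 * sps.norm.sf(z))


def tie_correction_term(values) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))
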