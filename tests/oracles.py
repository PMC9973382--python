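"""Independent brute-force oracles used to pin down expected values.

These deliberately re-derive every statistic from its definition with
plain loops, staying independent of the implementation code paths they
check.
"""

import itertools
import math

import numpy as np


# -- single-sample enrichment ------------------------------------------------

def ssgsea_oracle(values, gene_names, sig_genes, weight):
    """Area under the running enrichment statistic, evaluated literally.

    Genes are ranked (average ranks for ties), ranks divided by N, the
    walk visits genes in decreasing normalized rank (stable order), and
    ES = sum_i (P_hit(i) - P_miss(i)).
    """
    values = list(values)
    n = len(values)
    # average ranks
    order_asc = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_asc[j + 1]] == values[order_asc[i]]:
            j += 1
        avg = (i + j + 2) / 2.0
        for k in range(i, j + 1):
            ranks[order_asc[k]] = avg
        i = j + 1
    r = [rk / n for rk in ranks]
    walk = sorted(range(n), key=lambda i: -r[i])
    # stable: numpy argsort(-r, stable) keeps original order for ties
    walk = sorted(range(n), key=lambda i: (-r[i], i))
    hits = [gene_names[i] in sig_genes for i in walk]
    rw = [abs(r[i]) ** weight for i in walk]
    denom_hit = sum(w for w, h in zip(rw, hits) if h)
    n_miss = n - sum(hits)
    es = 0.0
    cum_hit = 0.0
    cum_miss = 0.0
    for w, h in zip(rw, hits):
        if h:
            cum_hit += w / denom_hit
        else:
            cum_miss += 1.0 / n_miss
        es += cum_hit - cum_miss
    return es


# -- rank-sum test -----------------------------------------------------------

def wilcoxon_enumeration(x, y):
    """Exact two-sided rank-sum p by full enumeration (no-ties data only)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    m, n = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - m * (m + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, m + n + 1), m):
        us.append(sum(combo) - m * (m + 1) / 2)
    us = np.array(us, dtype=float)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lower, upper))


def hodges_lehmann_oracle(x, y):
    diffs = sorted(xi - yi for xi in x for yi in y)
    k = len(diffs)
    if k % 2:
        return diffs[k // 2]
    return 0.5 * (diffs[k // 2 - 1] + diffs[k // 2])


# -- multiple testing --------------------------------------------------------

def bh_oracle(pvals):
    """Step-up BH adjustment, literal implementation."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# -- quantiles ---------------------------------------------------------------

def quantile_oracle(a, q):
    """Linear interpolation between order statistics (R type 7)."""
    s = sorted(a)
    n = len(s)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


# -- driver curation ---------------------------------------------------------

SYN = {"3'Flank", "3'UTR", "5'Flank", "5'UTR", "Intron", "RNA", "Silent"}


def driver_oracle(rows, sample_group, gene_list, silent_rule, hotspot_only):
    """Exhaustive re-application of the three driver rules per group.

    ``rows`` are dicts (sample, gene, variant_classification, is_hotspot).
    Returns the set of (gene, group) passes.
    """
    groups = sorted({g for g in sample_group.values()})
    passes = set()
    for grp in groups:
        grp_rows = [r for r in rows
                    if sample_group.get(r["sample"]) == grp
                    and r["gene"] in gene_list
                    and (not hotspot_only or r["is_hotspot"])]
        counts = {}
        for gene in gene_list:
            tumors = {r["sample"] for r in grp_rows
                      if r["gene"] == gene
                      and r["variant_classification"] not in SYN}
            counts[gene] = len(tumors)
        vals = sorted(counts.values())
        q1 = quantile_oracle(vals, 0.25)
        q3 = quantile_oracle(vals, 0.75)
        thr = q3 + 3 * (q3 - q1)
        for gene in gene_list:
            if not (counts[gene] > thr and counts[gene] >= 3):
                continue
            if silent_rule:
                all_g = [r for r in grp_rows if r["gene"] == gene]
                silent = [r for r in all_g
                          if r["variant_classification"] in SYN]
                if all_g and len(silent) / len(all_g) >= 0.20:
                    continue
            passes.add((gene, grp))
    return passes


# -- interval merging --------------------------------------------------------

def merge_overlaps_oracle(intervals):
    """Transitive closure of any-base-overlap merging (pairwise, to fixpoint)."""
    items = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] <= b[1] and b[0] <= a[1]:
                    merged = (min(a[0], b[0]), max(a[1], b[1]))
                    items = [items[k] for k in range(len(items))
                             if k not in (i, j)] + [merged]
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


# -- Plackett-Luce -----------------------------------------------------------

def pl_loglik(worths, orderings, weights=None):
    if weights is None:
        weights = [1.0] * len(orderings)
    ll = 0.0
    for order, wt in zip(orderings, weights):
        for s in range(len(order) - 1):
            remaining = order[s:]
            ll += wt * (math.log(worths[order[s]])
                        - math.log(sum(worths[i] for i in remaining)))
    return ll


def pl_grid_oracle(orderings, weights=None, steps=120):
    """Grid-search ML worths for 3 events on the normalized 2-simplex."""
    best = None
    for i in range(1, steps):
        for j in range(1, steps - i):
            w = (i / steps, j / steps, (steps - i - j) / steps)
            ll = pl_loglik(w, orderings, weights)
            if best is None or ll > best[0]:
                best = (ll, w)
    return best[1]


# -- survival ----------------------------------------------------------------

def logrank_oracle(times, events, groups):
    """Two-group log-rank chi-square by the observed-expected tabulation."""
    data = sorted(zip(times, events, groups))
    event_times = sorted({t for t, e, g in data if e == 1})
    labels = sorted(set(groups))
    assert len(labels) == 2
    O = {g: 0.0 for g in labels}
    E = {g: 0.0 for g in labels}
    V = 0.0
    for t in event_times:
        at_risk = {g: sum(1 for tt, e, gg in data if tt >= t and gg == g)
                   for g in labels}
        deaths = {g: sum(1 for tt, e, gg in data
                         if tt == t and e == 1 and gg == g)
                  for g in labels}
        n = sum(at_risk.values())
        d = sum(deaths.values())
        for g in labels:
            O[g] += deaths[g]
            E[g] += d * at_risk[g] / n
        if n > 1:
            V += (d * (at_risk[labels[0]] / n)
                  * (at_risk[labels[1]] / n) * (n - d) / (n - 1))
    g0 = labels[0]
    return (O[g0] - E[g0]) ** 2 / V


def km_oracle(times, events):
    """Product-limit estimate at each distinct event time."""
    data = sorted(zip(times, events))
    event_times = sorted({t for t, e in data if e == 1})
    surv = []
    s = 1.0
    for t in event_times:
        n = sum(1 for tt, e in data if tt >= t)
        d = sum(1 for tt, e in data if tt == t and e == 1)
        s *= (1 - d / n)
        surv.append((t, s))
    return surv
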