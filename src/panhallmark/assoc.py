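"""Cross-tumor-type association of somatic alterations with signature scores.

The core statistic: for every (alteration, signature, tumor type) a
two-sided Wilcoxon rank-sum test of altered vs wildtype signature
scores with a Hodges-Lehmann location estimate; directional counts of
significant tumor types per (alteration, signature) pair; and a
label-permutation FDR — alteration labels are shuffled within each
qualifying tumor type, the per-replicate count of significant
same-direction tumor types is compared with the observed count, and
the exceedance fraction is the FDR, BH-adjusted within an alteration
class.  A Gaussian GLM with subtype as covariate confirms
subtype-independence, and a chi-square enrichment test links binary
events to a sample status.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import (bh_adjust, rank_sum_p_exact_table, rank_sum_p_normal,
                     tie_correction_term, wilcoxon_rank_sum)
from .curation import AlterationMatrix
from .sigscore import SignatureScoreMatrix

log = logging.getLogger("panhallmark")

#: per-class Wilcoxon significance thresholds
DEFAULT_P_THRESHOLDS = {"mutation": 1e-3, "focal": 1e-3, "arm": 1e-7}


def _aligned(scores: SignatureScoreMatrix, alts: AlterationMatrix):
    samples = [s for s in scores.scores.columns if s in alts.values.index]
    if not samples:
        raise ValueError("no samples shared between scores and alterations")
    return samples


def wilcoxon_scan(scores: SignatureScoreMatrix, alts: AlterationMatrix,
                  type_labels: Mapping[str, str]) -> pd.DataFrame:
    """Per (alteration, signature, qualifying tumor type) Wilcoxon results.

    Alterations qualifying in fewer than two tumor types are excluded
    (logged); groups with fewer than two samples on either side are
    skipped.  Returns a long table with two-sided p and the
    Hodges-Lehmann estimate (altered - wildtype).
    """
    samples = _aligned(scores, alts)
    ttype = pd.Series({s: type_labels[s] for s in samples})
    rows = []
    for alt in alts.values.columns:
        qual = alts.meta.loc[alt, "qualifying_types"]
        if len(qual) < 2:
            log.info("alteration %s qualifies in <2 tumor types; excluded", alt)
            continue
        a = alts.values.loc[samples, alt]
        for t in qual:
            in_t = (ttype == t) & a.notna()
            altered = in_t.index[in_t & (a == 1)]
            wildtype = in_t.index[in_t & (a == 0)]
            if len(altered) < 2 or len(wildtype) < 2:
                log.debug("%s in %s skipped: group sizes %d/%d", alt, t,
                          len(altered), len(wildtype))
                continue
            for sig in scores.scores.index:
                x = scores.scores.loc[sig, altered].values
                y = scores.scores.loc[sig, wildtype].values
                p, est = wilcoxon_rank_sum(x, y)
                rows.append(dict(alteration=alt, signature=sig, tumor_type=t,
                                 n_altered=len(altered),
                                 n_wildtype=len(wildtype), p=p, estimate=est))
    return pd.DataFrame(rows, columns=["alteration", "signature", "tumor_type",
                                       "n_altered", "n_wildtype", "p",
                                       "estimate"])


def count_directional(results: pd.DataFrame, p_threshold: float,
                      min_count: int = 2) -> pd.DataFrame:
    """Directional counts of significant tumor types per (alteration, signature).

    A tumor type counts up iff p <= threshold and estimate > 0, down iff
    p <= threshold and estimate < 0; a zero estimate with significant p
    counts in neither direction (warned).  Pairs whose larger count is
    below ``min_count`` are flagged non-candidates.
    """
    rows = []
    if results.empty:
        return pd.DataFrame(columns=["alteration", "signature", "direction",
                                     "count", "tested", "candidate"])
    zero_sig = (results["p"] <= p_threshold) & (results["estimate"] == 0)
    if zero_sig.any():
        log.warning("%d significant results with zero estimate counted in "
                    "neither direction", int(zero_sig.sum()))
    for (alt, sig), grp in results.groupby(["alteration", "signature"],
                                           sort=True):
        sig_mask = grp["p"] <= p_threshold
        up = int((sig_mask & (grp["estimate"] > 0)).sum())
        down = int((sig_mask & (grp["estimate"] < 0)).sum())
        tested = len(grp)
        candidate = max(up, down) >= min_count
        for direction, count in (("up", up), ("down", down)):
            rows.append(dict(alteration=alt, signature=sig,
                             direction=direction, count=count, tested=tested,
                             candidate=candidate and count >= min_count))
    return pd.DataFrame(rows)


def _replicate_counts(score_mat: np.ndarray, ttype: np.ndarray,
                      alt_vals: np.ndarray, qual: Sequence[str],
                      p_threshold: float, n_perm: int,
                      rng: np.random.Generator):
    """Per-replicate counts of significant up/down tumor types.

    For each qualifying tumor type the alteration labels are shuffled
    (preserving the type's alteration frequency); significance uses the
    same p conventions as the observed scan (exact when both groups
    <= 12 and no ties, else tie-corrected normal approximation), and the
    direction is the sign of the rank-sum location U - mn/2.
    Returns (up_counts, down_counts) of shape (n_signatures, n_perm).
    """
    n_sig = score_mat.shape[0]
    up = np.zeros((n_sig, n_perm), dtype=np.int32)
    down = np.zeros((n_sig, n_perm), dtype=np.int32)
    for t in qual:
        in_t = np.flatnonzero((ttype == t) & ~np.isnan(alt_vals))
        a = alt_vals[in_t]
        m = int(a.sum())
        n_all = in_t.size
        n_w = n_all - m
        if m < 2 or n_w < 2:
            continue
        X = score_mat[:, in_t]
        ranks = sps.rankdata(X, axis=1)
        # random masks with exactly m altered per replicate
        draw = rng.random((n_perm, n_all))
        idx = np.argpartition(draw, m - 1, axis=1)[:, :m]
        M = np.zeros((n_perm, n_all))
        np.put_along_axis(M, idx, 1.0, axis=1)
        R1 = ranks @ M.T  # (n_sig, n_perm) rank sums of the altered group
        U = R1 - m * (m + 1) / 2.0
        exact_ok = m <= 12 and n_w <= 12
        table = rank_sum_p_exact_table(m, n_w) if exact_ok else None
        for k in range(n_sig):
            tie_term = tie_correction_term(X[k])
            if exact_ok and tie_term == 0:
                p = table[np.round(U[k]).astype(int)]
            else:
                p = rank_sum_p_normal(U[k], m, n_w, tie_term)
            sig_mask = p <= p_threshold
            direction = U[k] - m * n_w / 2.0
            up[k] += sig_mask & (direction > 0)
            down[k] += sig_mask & (direction < 0)
    return up, down


def permutation_consistency_fdr(scores: SignatureScoreMatrix,
                                alts: AlterationMatrix,
                                candidates: pd.DataFrame,
                                type_labels: Mapping[str, str],
                                n_perm: int = 10_000,
                                p_threshold: float | Mapping[str, float] = None,
                                seed: int = 0,
                                pseudocount: bool = False) -> pd.DataFrame:
    """Label-permutation FDR for cross-tumor-type consistency.

    ``candidates`` rows need (alteration, signature, direction, count);
    rows with count 0 are not tested.  Per candidate, each permutation
    replicate shuffles alteration labels independently within each
    qualifying tumor type and counts significant same-direction tumor
    types; FDR = #(replicate count >= observed)/n_perm (optionally the
    (b+1)/(n+1) pseudocount).  BH adjustment runs within each alteration
    class.  Same seed gives identical output.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cands = candidates[candidates["count"] > 0].copy()
    if cands.empty:
        return pd.DataFrame(columns=["alteration", "signature", "direction",
                                     "count", "tested", "fdr", "fdr_bh",
                                     "alteration_class"])
    samples = _aligned(scores, alts)
    score_mat = scores.scores[samples].values
    sig_index = {s: i for i, s in enumerate(scores.scores.index)}
    ttype = np.array([type_labels[s] for s in samples])
    rng = np.random.default_rng(seed)
    fdrs = []
    classes = []
    for alt in sorted(cands["alteration"].unique()):
        sub = cands[cands["alteration"] == alt]
        qual = alts.meta.loc[alt, "qualifying_types"]
        alt_vals = alts.values.loc[samples, alt].values.astype(float)
        up, down = _replicate_counts(score_mat, ttype, alt_vals, qual,
                                     _thr_for(p_threshold, alts, alt),
                                     n_perm, rng)
        for _, row in sub.iterrows():
            counts = up if row["direction"] == "up" else down
            b = int((counts[sig_index[row["signature"]]] >= row["count"]).sum())
            fdr = (b + 1) / (n_perm + 1) if pseudocount else b / n_perm
            fdrs.append((row["alteration"], row["signature"], row["direction"],
                         row["count"], row["tested"], fdr))
            classes.append(alts.meta.loc[alt, "alteration_class"])
    out = pd.DataFrame(fdrs, columns=["alteration", "signature", "direction",
                                      "count", "tested", "fdr"])
    out["alteration_class"] = classes
    out["fdr_bh"] = np.nan
    for cls, grp in out.groupby("alteration_class"):
        out.loc[grp.index, "fdr_bh"] = bh_adjust(grp["fdr"].values)
    return out


def _thr_for(p_threshold, alts, alt):
    if p_threshold is None:
        return DEFAULT_P_THRESHOLDS[alts.meta.loc[alt, "alteration_class"]]
    if isinstance(p_threshold, Mapping):
        return p_threshold[alts.meta.loc[alt, "alteration_class"]]
    return float(p_threshold)


def subtype_adjusted_glm(scores: SignatureScoreMatrix, alts: AlterationMatrix,
                         subtype_labels: Mapping[str, str],
                         type_labels: Mapping[str, str],
                         tumor_type: str,
                         alterations: Sequence[str] | None = None,
                         ) -> pd.DataFrame:
    """Gaussian GLM: signature ~ alteration + subtype, within one tumor type.

    Records the alteration-coefficient estimate and p per (alteration,
    signature); an alteration perfectly collinear with subtype is
    flagged inestimable.  BH adjustment is applied across the returned
    triples (re-adjust across tumor types with ``adjust_glm_records``
    when scanning several types).
    """
    import statsmodels.api as sm

    samples = [s for s in _aligned(scores, alts)
               if type_labels[s] == tumor_type]
    subs = pd.Series({s: subtype_labels[s] for s in samples})
    if subs.nunique() < 2:
        raise ValueError(f"tumor type {tumor_type} has <2 subtypes")
    dummies = pd.get_dummies(subs, drop_first=True, dtype=float)
    rows = []
    for alt in (alterations if alterations is not None
                else alts.values.columns):
        a = alts.values.loc[samples, alt].astype(float)
        ok = a.notna()
        if a[ok].nunique() < 2:
            continue  # both groups must be non-empty
        # perfectly collinear with subtype <=> constant within every subtype
        inestimable = all(a[ok][subs[ok] == s].nunique() <= 1
                          for s in subs[ok].unique())
        for sig in scores.scores.index:
            if inestimable:
                rows.append(dict(alteration=alt, signature=sig,
                                 tumor_type=tumor_type, estimate=np.nan,
                                 p=np.nan, inestimable=True))
                continue
            y = scores.scores.loc[sig, samples][ok].values
            X = pd.concat([a[ok].rename("alteration"), dummies.loc[ok.index[ok]]],
                          axis=1)
            X = sm.add_constant(X.values.astype(float))
            fit = sm.OLS(y, X).fit()
            rows.append(dict(alteration=alt, signature=sig,
                             tumor_type=tumor_type,
                             estimate=float(fit.params[1]),
                             p=float(fit.pvalues[1]), inestimable=False))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = bh_adjust(out["p"].values)
    return out


def adjust_glm_records(records: pd.DataFrame) -> pd.DataFrame:
    """Re-run BH across all (alteration, signature, tumor type) triples."""
    out = records.copy()
    out["p_bh"] = bh_adjust(out["p"].values)
    return out


def group_enrichment(binary_events: AlterationMatrix,
                     status: Mapping[str, int]) -> pd.DataFrame:
    """Chi-square enrichment of each binary event in status-positive samples.

    Odds ratios use the Haldane-Anscombe 0.5 correction when any cell of
    the 2x2 table is zero; p-values are BH-adjusted across events.
    Events with zero carriers are skipped.
    """
    samples = [s for s in binary_events.values.index if s in status]
    st = np.array([status[s] for s in samples], dtype=float)
    rows = []
    for ev in binary_events.values.columns:
        a = binary_events.values.loc[samples, ev].values.astype(float)
        ok = ~np.isnan(a)
        tab = np.array([
            [np.sum((a[ok] == 1) & (st[ok] == 1)),
             np.sum((a[ok] == 1) & (st[ok] == 0))],
            [np.sum((a[ok] == 0) & (st[ok] == 1)),
             np.sum((a[ok] == 0) & (st[ok] == 0))],
        ])
        if tab[0].sum() == 0:
            log.info("event %s has zero carriers; skipped", ev)
            continue
        if (tab == 0).any():
            c = tab + 0.5
        else:
            c = tab
        odds = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            p = 1.0  # degenerate margin: no contrast to test
        else:
            p = float(sps.chi2_contingency(tab, correction=True)[1])
        rows.append(dict(event=ev, odds_ratio=float(odds), p=p,
                         n_carriers=int(tab[0].sum())))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = bh_adjust(out["p"].values)
    return out
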