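"""Single-sample GSEA projection of expression onto gene signatures.

Per sample, genes are rank-normalized (average ranks for ties, divided
by the number of genes) and the enrichment score of a signature is the
area under the running enrichment statistic,

    ES = sum_i [ P_hit(i) - P_miss(i) ],

where the walk visits genes in decreasing rank order, P_hit weights
signature genes by |r_i|^w (w = 0.75 by default) and P_miss is the
uniform ECDF over non-signature genes.  Because only ranks enter, the
score is invariant to any per-sample strictly increasing transform of
expression.  An optional permutation normalization divides ES by the
mean |ES| over random gene-label assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust, iqr
from .io_formats import ExpressionMatrix, SignatureSet

log = logging.getLogger("panhallmark")


@dataclass
class SignatureScoreMatrix:
    """Signatures x samples enrichment scores plus the parameters used."""

    scores: pd.DataFrame
    params: dict

    def __post_init__(self):
        if not np.isfinite(self.scores.values).all():
            raise ValueError("non-finite enrichment scores")
        for key in ("weight", "min_overlap", "normalization"):
            if key not in self.params:
                raise ValueError(f"parameter record incomplete: missing {key}")


@dataclass
class LowVariabilityResult:
    retained: list
    removed: list
    median_iqr: pd.Series


def _rank_normalize(col: np.ndarray) -> np.ndarray:
    """Average ranks divided by the number of genes."""
    return sps.rankdata(col, method="average") / col.size


def _es_one_sample(r: np.ndarray, hit_masks: np.ndarray,
                   weight: float) -> np.ndarray:
    """Enrichment scores of all signatures for one sample.

    ``r``: normalized rank per gene; ``hit_masks``: signatures x genes
    boolean.  Walk order is decreasing rank (stable for ties).
    """
    order = np.argsort(-r, kind="stable")
    rw = np.abs(r[order]) ** weight
    hits = hit_masks[:, order]
    n = r.size
    hit_w = np.where(hits, rw[None, :], 0.0)
    denom_hit = hit_w.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(hit_w, axis=1) / denom_hit
    n_miss = n - hits.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~hits, axis=1) / n_miss
    return (p_hit - p_miss).sum(axis=1)


def ssgsea_scores(expr: ExpressionMatrix, sigs: Sequence[SignatureSet],
                  weight: float = 0.75, min_overlap: int = 5,
                  normalize: str = "raw", n_perm: int = 1000,
                  seed: int | None = 0) -> SignatureScoreMatrix:
    """Score every sample against every signature.

    Signatures overlapping the expression genes by fewer than
    ``min_overlap`` genes are dropped with a warning.  ``normalize`` is
    "raw" (area under RES, default) or "perm" (divide by the mean |ES|
    over ``n_perm`` random gene-label assignments of the same set size).
    """
    genes = list(expr.gene_ids)
    if not genes or expr.values.shape[1] == 0:
        raise ValueError("empty expression matrix")
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    kept, masks = [], []
    for s in sigs:
        pos = [gene_pos[g] for g in s.genes if g in gene_pos]
        if len(pos) < min_overlap:
            log.warning("signature %s: overlap %d < min_overlap %d; dropped",
                        s.name, len(pos), min_overlap)
            continue
        if len(pos) == n:
            raise ValueError(
                f"signature {s.name} covers the whole gene universe; "
                "miss set empty")
        mask = np.zeros(n, dtype=bool)
        mask[pos] = True
        kept.append(s.name)
        masks.append(mask)
    if not kept:
        raise ValueError("no signature overlaps the expression genes by "
                         f">= {min_overlap}")
    hit_masks = np.vstack(masks)
    values = expr.values.values
    out = np.empty((len(kept), values.shape[1]))
    for j in range(values.shape[1]):
        r = _rank_normalize(values[:, j])
        out[:, j] = _es_one_sample(r, hit_masks, weight)
    if normalize == "perm":
        rng = np.random.default_rng(seed)
        sizes = hit_masks.sum(axis=1)
        scale = np.empty(len(kept))
        # null |ES| depends only on set size given the rank vector; use the
        # pooled average rank profile of the matrix's first sample ranks
        for k, size in enumerate(sizes):
            es = np.empty(n_perm)
            r = _rank_normalize(values[:, 0])
            for b in range(n_perm):
                pos = rng.choice(n, size=size, replace=False)
                m = np.zeros(n, dtype=bool)
                m[pos] = True
                es[b] = _es_one_sample(r, m[None, :], weight)[0]
            scale[k] = np.mean(np.abs(es))
        out = out / scale[:, None]
    elif normalize != "raw":
        raise ValueError(f"unknown normalization {normalize!r}")
    scores = pd.DataFrame(out, index=pd.Index(kept, name="signature"),
                          columns=expr.sample_ids)
    return SignatureScoreMatrix(scores, dict(weight=weight,
                                             min_overlap=min_overlap,
                                             normalization=normalize))


def filter_low_variability_signatures(scores: SignatureScoreMatrix,
                                      subtype_labels: Mapping[str, str],
                                      iqr_floor: float) -> LowVariabilityResult:
    """Remove signatures whose median within-subtype IQR falls below the floor.

    Makes explicit the by-inspection removal of near-constant, lowly
    expressed signatures: for each signature the IQR is computed within
    every subtype and the signature is removed iff the median of those
    IQRs is below ``iqr_floor``.
    """
    if iqr_floor < 0:
        raise ValueError("iqr_floor must be non-negative")
    df = scores.scores
    sub = pd.Series({s: subtype_labels[s] for s in df.columns})
    for subtype, members in sub.groupby(sub):
        if len(members) < 2:
            raise ValueError(f"subtype {subtype!r} has fewer than 2 samples")
    med_iqr = {}
    for sig in df.index:
        iqrs = [iqr(df.loc[sig, members.index].values)
                for _, members in sub.groupby(sub)]
        med_iqr[sig] = float(np.median(iqrs))
    med_iqr = pd.Series(med_iqr, name="median_within_subtype_iqr")
    removed = list(med_iqr.index[med_iqr < iqr_floor])
    retained = [s for s in df.index if s not in removed]
    if removed:
        log.info("removed low-variability signatures: %s", removed)
    return LowVariabilityResult(retained, removed, med_iqr)


def signature_similarity(scores: SignatureScoreMatrix,
                         sigs: Sequence[SignatureSet]) -> pd.DataFrame:
    """All unordered signature pairs with Pearson r, BH-adjusted p and Jaccard.

    Zero-variance signatures give undefined correlations; those pairs are
    recorded with missing r/p and excluded from the BH family.
    """
    df = scores.scores
    if df.shape[0] < 2 or df.shape[1] < 3:
        raise ValueError("need >=2 signatures and >=3 samples")
    gene_sets = {s.name: s.gene_set for s in sigs}
    names = list(df.index)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            x, y = df.loc[a].values, df.loc[b].values
            if np.std(x) == 0 or np.std(y) == 0:
                r = p = np.nan
            else:
                r, p = sps.pearsonr(x, y)
            ja = jb = None
            jac = np.nan
            if a in gene_sets and b in gene_sets:
                ja, jb = gene_sets[a], gene_sets[b]
                jac = len(ja & jb) / len(ja | jb)
            rows.append(dict(sig_a=a, sig_b=b, pearson_r=r, p=p, jaccard=jac))
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].values)
    return out
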