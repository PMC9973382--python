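"""Subtype-level clustering of signature/CNA profiles and marker tests.

Subtype mean matrices (size-filtered, median-centered rows) are
clustered agglomeratively on the correlation dissimilarity d = 1 - r
with a Ward criterion.  Both classic Ward variants are available:
"wardD" applies the Lance-Williams recurrence to d directly, "wardD2"
(default) to squared dissimilarities with square-root merge heights.
Clusters are read off the dendrogram below a cut height, and each
cluster's marker signatures come from a one-vs-rest Welch t statistic
with a label-permutation null and BH q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .sigscore import SignatureScoreMatrix

log = logging.getLogger("panhallmark")


@dataclass
class SubtypeMatrix:
    """Features x subtypes means with per-subtype sample counts."""

    values: pd.DataFrame
    sample_counts: pd.Series
    centering: str = "median"
    excluded: pd.DataFrame | None = None


@dataclass
class ClusterAssignment:
    """Subtype -> cluster id (contiguous from 1) plus the dendrogram."""

    labels: pd.Series
    merges: pd.DataFrame  # left, right, height, size (nodes < n are leaves)
    cut_height: float
    linkage: str

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def subtype_mean_matrix(scores: SignatureScoreMatrix,
                        type_labels: Mapping[str, str],
                        subtype_labels: Mapping[str, str],
                        min_type_n: int = 100,
                        min_subtype_n: int = 10) -> SubtypeMatrix:
    """Per-subtype feature means, median-centered across subtypes.

    Tumor types with fewer than ``min_type_n`` samples and subtypes with
    ``min_subtype_n`` samples or fewer are excluded (strict >).  Samples
    without a subtype fall back to their tumor type as the subtype id.
    """
    df = scores.scores
    ttype = pd.Series({s: type_labels[s] for s in df.columns})
    sub = pd.Series({
        s: subtype_labels.get(s) if _present(subtype_labels.get(s))
        else ttype[s]
        for s in df.columns})
    type_counts = ttype.value_counts()
    cols, counts, excluded = {}, {}, []
    for subtype, members in sub.groupby(sub):
        idx = members.index
        t = ttype[idx[0]]
        if type_counts[t] < min_type_n:
            excluded.append((subtype, len(idx), f"tumor type {t} has "
                             f"{type_counts[t]} < {min_type_n} samples"))
            continue
        if len(idx) <= min_subtype_n:
            excluded.append((subtype, len(idx),
                             f"subtype has <= {min_subtype_n} samples"))
            continue
        cols[subtype] = df[idx].mean(axis=1)
        counts[subtype] = len(idx)
    if not cols:
        raise ValueError("no subtype survives the size rules")
    mat = pd.DataFrame(cols)
    mat = mat.sub(mat.median(axis=1), axis=0)
    return SubtypeMatrix(mat, pd.Series(counts), "median",
                         pd.DataFrame(excluded, columns=["subtype", "n",
                                                         "reason"]))


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and np.isnan(v))


def correlation_dissimilarity(matrix: pd.DataFrame) -> np.ndarray:
    """d = 1 - Pearson r between column profiles."""
    v = matrix.values
    if (v.std(axis=0) == 0).any():
        bad = matrix.columns[v.std(axis=0) == 0]
        raise ValueError(f"zero-variance column(s): {list(bad)}")
    return 1.0 - np.corrcoef(v, rowvar=False)


def _lance_williams_ward(d: np.ndarray, squared: bool):
    """Agglomerative Ward merges via the Lance-Williams recurrence.

    ``squared`` selects the ward.D2-style criterion (recurrence on d^2,
    heights reported as sqrt); otherwise the recurrence runs on d
    directly (ward.D).  Ties break on the lowest pair of node indices.
    Returns a merge table (left, right, height, size) with leaves
    0..n-1 and internal nodes n..2n-2.
    """
    n = d.shape[0]
    D = d.astype(float) ** 2 if squared else d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = {i: (i, 1) for i in range(n)}  # slot -> (node id, size)
    merges = []
    next_id = n
    for _ in range(n - 1):
        slots = sorted(active)
        best = None
        for ii, i in enumerate(slots):
            for j in slots[ii + 1:]:
                if best is None or D[i, j] < best[0] - 1e-15:
                    best = (D[i, j], i, j)
        h, i, j = best
        ni, nj = active[i][1], active[j][1]
        height = float(np.sqrt(h)) if squared else float(h)
        merges.append((active[i][0], active[j][0], height, ni + nj))
        for k in slots:
            if k in (i, j):
                continue
            nk = active[k][1]
            tot = ni + nj + nk
            D[i, k] = D[k, i] = ((ni + nk) * D[i, k] + (nj + nk) * D[j, k]
                                 - nk * h) / tot
        active[i] = (next_id, ni + nj)
        del active[j]
        D[j, :] = D[:, j] = np.inf
        next_id += 1
    return pd.DataFrame(merges, columns=["left", "right", "height", "size"])


def hierarchical_cut(matrix: SubtypeMatrix | pd.DataFrame, cut_height: float,
                     linkage: str = "wardD2") -> ClusterAssignment:
    """Cluster columns on 1 - r with Ward linkage; cut the tree at a height.

    Clusters are the connected groups whose merges all lie strictly
    below ``cut_height``; merges at or above the cut are not applied.
    A cut at or below 0 leaves every column its own cluster; a cut above
    the maximum merge height yields a single cluster.
    """
    mat = matrix.values if isinstance(matrix, SubtypeMatrix) else matrix
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    if linkage not in ("wardD", "wardD2"):
        raise ValueError(f"unknown linkage {linkage!r}")
    d = correlation_dissimilarity(mat)
    merges = _lance_williams_ward(d, squared=(linkage == "wardD2"))
    n = mat.shape[1]
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for node, (_, row) in enumerate(merges.iterrows(), start=n):
        if row["height"] < cut_height:
            parent[find(int(row["left"]))] = node
            parent[find(int(row["right"]))] = node

    roots = {}
    labels = {}
    for i, col in enumerate(mat.columns):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[col] = roots[r]
    return ClusterAssignment(pd.Series(labels, name="cluster"), merges,
                             float(cut_height), linkage)


def cluster_marker_test(scores: pd.DataFrame,
                        cluster_of_sample: Mapping[str, int],
                        n_perm: int = 10_000, q_display: float = 1e-4,
                        seed: int = 0) -> pd.DataFrame:
    """One-vs-rest permuted Welch t test of each feature per cluster.

    The null comes from ``n_perm`` random reassignments of the cluster
    labels (one permutation shared across features per replicate, which
    preserves feature correlation); permutation p uses the (b+1)/(B+1)
    convention; q-values are BH within a cluster across features.  Fold
    change is the mean difference (cluster - rest).  Rows significant at
    q < ``q_display`` are flagged ``display``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    samples = [s for s in scores.columns if s in cluster_of_sample]
    labels = np.array([cluster_of_sample[s] for s in samples])
    X = scores[samples].values  # features x samples
    clusters = np.unique(labels)
    for c in clusters:
        if (labels == c).sum() < 2:
            raise ValueError(f"cluster {c} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels.size) for _ in range(n_perm)])
    rows = []
    for c in clusters:
        mask = labels == c
        t_obs, fc = _welch_rows(X, mask)
        # permuted statistics: same membership size, random samples
        exceed = np.zeros(X.shape[0])
        for b in range(n_perm):
            pm = np.zeros(labels.size, dtype=bool)
            pm[perms[b, : mask.sum()]] = True
            t_b, _ = _welch_rows(X, pm)
            exceed += np.abs(t_b) >= np.abs(t_obs)
        p = (exceed + 1.0) / (n_perm + 1.0)
        q = bh_adjust(p)
        for k, feat in enumerate(scores.index):
            rows.append(dict(cluster=int(c), feature=feat,
                             fold_change=float(fc[k]), t=float(t_obs[k]),
                             p=float(p[k]), q=float(q[k]),
                             display=bool(q[k] < q_display)))
    return pd.DataFrame(rows)


def _welch_rows(X: np.ndarray, mask: np.ndarray):
    """Row-wise Welch t statistic and mean difference, group mask vs rest."""
    a, b = X[:, mask], X[:, ~mask]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / mask.sum()
    vb = b.var(axis=1, ddof=1) / (~mask).sum()
    denom = np.sqrt(va + vb)
    denom[denom == 0] = np.nan
    t = (ma - mb) / denom
    return np.nan_to_num(t), ma - mb
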