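"""Chronological ordering of somatic events from CCF-based partial rankings.

Within each tumor, observed somatic events (mutations, arm gains and
losses, whole-genome doubling) are ordered by descending cancer cell
fraction — an event present in more of the tumor's cells is inferred to
have happened earlier.  The resulting partial rankings across tumors
feed a Plackett-Luce model: each event has a positive worth, and a
ranking arises by repeatedly selecting the next-earliest event with
probability proportional to worth.  Maximum-likelihood worths are found
by minorization-maximization (MM) iterations, regularized with a pair
of pseudo-rankings at small weight so the comparison graph is always
connected and the MLE finite.  Tumor-level bootstrap resampling gives a
95% CI on each event's inferred rank position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("panhallmark")


@dataclass
class EventOrderMatrix:
    """Tumors x events rank positions (1 = earliest); NaN = not observed.

    Tied events share a rank (dense ranks: 1, 1, 2, ...).
    """

    ranks: pd.DataFrame

    def __post_init__(self):
        for tumor, row in self.ranks.iterrows():
            present = sorted(row.dropna().values)
            if len(present) < 2:
                raise ValueError(f"tumor {tumor} ranks <2 events")
            uniq = sorted(set(present))
            if uniq != list(range(1, len(uniq) + 1)):
                raise ValueError(f"tumor {tumor}: ranks must be dense from 1")

    @property
    def events(self) -> list:
        return list(self.ranks.columns)


@dataclass
class WorthEstimate:
    """Fitted Plackett-Luce worths (normalized to sum 1) and the implied order."""

    worths: pd.Series
    order: list
    iterations: int
    converged: bool
    log_likelihood: float
    loglik_trace: np.ndarray
    tie_policy: str = "random-split"
    rank_ci: pd.DataFrame | None = None


def build_rankings(events_per_tumor: pd.DataFrame,
                   clonality: pd.DataFrame | None = None) -> EventOrderMatrix:
    """Order each tumor's events by descending CCF; equal CCFs tie.

    ``events_per_tumor`` has columns (tumor, event, ccf) with CCF in
    [0, 1].  Tumors with fewer than two events are dropped with a
    warning.
    """
    df = events_per_tumor
    if ((df["ccf"] < 0) | (df["ccf"] > 1)).any():
        raise ValueError("CCF outside [0, 1]")
    events = sorted(df["event"].unique())
    rows = {}
    n_dropped = 0
    for tumor, grp in df.groupby("tumor", sort=True):
        if len(grp) < 2:
            n_dropped += 1
            continue
        # dense rank of -ccf: highest CCF -> rank 1; ties share a rank
        r = grp.set_index("event")["ccf"].rank(ascending=False,
                                               method="dense")
        rows[tumor] = r
    if n_dropped:
        log.warning("%d single-event tumors dropped", n_dropped)
    if not rows:
        raise ValueError("no tumor with >= 2 events")
    ranks = pd.DataFrame(rows).T.reindex(columns=events)
    ranks.index.name = "tumor"
    return EventOrderMatrix(ranks)


def _tumor_arrays(ranks: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per tumor: (event indices, rank values) over observed events."""
    vals = ranks.values.astype(float)
    out = []
    for i in range(vals.shape[0]):
        present = np.flatnonzero(~np.isnan(vals[i]))
        out.append((present, vals[i, present]))
    return out


def _orderings_from_arrays(tumors, rng: np.random.Generator) -> list[np.ndarray]:
    """Tie-broken orderings as event-index arrays (random-split policy)."""
    return [ev[np.lexsort((rng.random(ev.size), rk))] for ev, rk in tumors]


def _orderings_from_ranks(ranks: pd.DataFrame,
                          rng: np.random.Generator) -> list[np.ndarray]:
    return _orderings_from_arrays(_tumor_arrays(ranks), rng)


def _mm_fit(orderings: Sequence[Sequence[int]], weights: Sequence[float],
            n_events: int, max_iter: int, tol: float):
    """Hunter's MM iterations for Plackett-Luce worths.

    Each ordering contributes stages: at stage s, the item in position s
    is chosen from the set of items ranked s or later; the final
    single-item stage is uninformative and skipped.
    """
    w = np.ones(n_events) / n_events
    wins = np.zeros(n_events)
    chosen_list, wt_list, member_rows = [], [], []
    for order, wt in zip(orderings, weights):
        for s in range(len(order) - 1):
            chosen = order[s]
            row = np.zeros(n_events)
            row[order[s:]] = 1.0
            member_rows.append(row)
            chosen_list.append(chosen)
            wt_list.append(wt)
            wins[chosen] += wt
    if (wins == 0).any():
        never = np.flatnonzero(wins == 0)
        raise ValueError(
            f"events never chosen ahead of another (indices {list(never)}); "
            "comparison graph not strongly connected — increase epsilon")
    members = np.vstack(member_rows)  # stages x events indicator
    chosen_idx = np.array(chosen_list)
    wts = np.array(wt_list)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tot = members @ w  # remaining-set worth sums, one per stage
        trace.append(float(np.sum(wts * (np.log(w[chosen_idx])
                                         - np.log(tot)))))
        denom = members.T @ (wts / tot)
        new_w = wins / denom
        new_w = new_w / new_w.sum()
        delta = np.max(np.abs(new_w - w) / np.maximum(w, 1e-300))
        w = new_w
        if delta < tol:
            converged = True
            break
    tot = members @ w
    trace.append(float(np.sum(wts * (np.log(w[chosen_idx]) - np.log(tot)))))
    return w, it, converged, np.array(trace)


def _pseudo_rankings(n_events: int, epsilon: float):
    """One complete ranking and its reverse at weight epsilon."""
    forward = list(range(n_events))
    return [forward, forward[::-1]], [epsilon, epsilon]


def fit_plackett_luce(rankings: EventOrderMatrix, max_iter: int = 2000,
                      tol: float = 1e-8, tie_policy: str = "random-split",
                      epsilon: float = 0.1, seed: int = 0) -> WorthEstimate:
    """Maximum-likelihood Plackett-Luce worths by MM iterations.

    Tie groups are broken uniformly at random (seeded) under the default
    "random-split" policy.  A pseudo-observation of one complete ranking
    and its reverse at weight ``epsilon`` regularizes the fit,
    guaranteeing a connected comparison graph and a finite MLE.  Worths
    are normalized to sum 1; the inferred order is descending worth.
    """
    if tie_policy != "random-split":
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    rng = np.random.default_rng(seed)
    events = rankings.events
    orderings = _orderings_from_ranks(rankings.ranks, rng)
    weights = [1.0] * len(orderings)
    if epsilon > 0:
        po, pw = _pseudo_rankings(len(events), epsilon)
        orderings = orderings + po
        weights = weights + pw
    w, it, converged, trace = _mm_fit(orderings, weights, len(events),
                                      max_iter, tol)
    worths = pd.Series(w, index=events, name="worth")
    order = list(worths.sort_values(ascending=False, kind="stable").index)
    return WorthEstimate(worths, order, it, converged, float(trace[-1]),
                         trace, tie_policy)


def bootstrap_timing_ci(rankings: EventOrderMatrix, B: int = 1000,
                        seed: int = 0, epsilon: float = 0.1,
                        max_iter: int = 2000, tol: float = 1e-6,
                        ) -> pd.DataFrame:
    """95% CI of each event's inferred rank position by tumor bootstrap.

    ``B`` resamples of tumors with replacement; the Plackett-Luce fit is
    repeated per replicate (with a fresh random tie split) and the
    2.5th/97.5th percentiles of each event's rank position (1 = earliest)
    are reported.  Replicates whose fit fails are skipped and counted.
    """
    n_tumors = rankings.ranks.shape[0]
    if n_tumors < 5:
        raise ValueError("bootstrap needs >= 5 tumors")
    events = rankings.events
    rng = np.random.default_rng(seed)
    positions = np.full((B, len(events)), np.nan)
    skipped = 0
    tumors = _tumor_arrays(rankings.ranks)
    for b in range(B):
        take = rng.integers(0, n_tumors, size=n_tumors)
        boot = [tumors[i] for i in take]
        try:
            orderings = _orderings_from_arrays(boot, rng)
            weights = [1.0] * len(orderings)
            po, pw = _pseudo_rankings(len(events), epsilon)
            w, _, _, _ = _mm_fit(orderings + po, weights + pw, len(events),
                                 max_iter, tol)
        except ValueError:
            skipped += 1
            continue
        order = np.argsort(-w, kind="stable")
        pos = np.empty(len(events))
        pos[order] = np.arange(1, len(events) + 1)
        positions[b] = pos
    if skipped:
        log.warning("%d/%d bootstrap replicates skipped (disconnected fit)",
                    skipped, B)
    ok = ~np.isnan(positions[:, 0])
    lo = np.percentile(positions[ok], 2.5, axis=0)
    hi = np.percentile(positions[ok], 97.5, axis=0)
    mean = positions[ok].mean(axis=0)
    return pd.DataFrame({"event": events, "mean_rank": mean,
                         "ci_low": lo, "ci_high": hi,
                         "n_replicates": int(ok.sum())}).set_index("event")
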