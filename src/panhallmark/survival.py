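"""Signature-stratified survival analysis.

Quartile binarization of signature scores (high iff score >= the third
quartile of its group, per tumor type or dataset-wide), Kaplan-Meier
curves with the log-rank test under administrative censoring, and the
univariate-screen -> multivariate Cox proportional-hazards workflow:
every candidate covariate gets a univariate fit with a likelihood-ratio
p, and those passing the gate enter one multivariate model.  Event-time
ties use the Efron approximation (the lifelines default).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from ._stats import quantile
from .sigscore import SignatureScoreMatrix

log = logging.getLogger("panhallmark")


def binarize_by_quartile(scores: SignatureScoreMatrix, signature: str,
                         type_labels: Mapping[str, str] | None = None,
                         grouping: str = "per-type") -> pd.Series:
    """High/low labels: high iff score >= Q3 of its group.

    ``grouping`` is "per-type" (quartiles within each tumor type; needs
    ``type_labels``) or "global" (dataset-wide quartiles).  Groups with
    fewer than 4 samples are skipped with a warning (their samples get
    no label).
    """
    row = scores.scores.loc[signature]
    if grouping == "global":
        groups = pd.Series("all", index=row.index)
    elif grouping == "per-type":
        if type_labels is None:
            raise ValueError("per-type grouping needs type_labels")
        groups = pd.Series({s: type_labels[s] for s in row.index})
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = pd.Series(np.nan, index=row.index, name=f"{signature}_high")
    for g, members in groups.groupby(groups):
        idx = members.index
        if len(idx) < 4:
            log.warning("group %s has %d < 4 samples; skipped", g, len(idx))
            continue
        q3 = quantile(row[idx].values, 0.75)
        out[idx] = (row[idx] >= q3).astype(float)
    return out


def km_logrank(clinical: pd.DataFrame, group_labels: Mapping[str, object],
               censor_horizon: float = 10.0) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test across groups.

    Times above ``censor_horizon`` are administratively censored at the
    horizon.  Returns a dict with per-group survival curves, the
    log-rank chi-square, degrees of freedom and p.
    """
    samples = [s for s in clinical.index if s in group_labels
               and _notna(group_labels[s])]
    if not samples:
        raise ValueError("no labelled samples")
    df = clinical.loc[samples, ["time", "event"]].copy()
    over = df["time"] > censor_horizon
    df.loc[over, "event"] = 0
    df.loc[over, "time"] = censor_horizon
    df["group"] = [group_labels[s] for s in samples]
    counts = df.groupby("group").size()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("need >= 2 non-empty groups")
    if int(df["event"].sum()) == 0:
        raise ValueError("no events after censoring")
    curves = {}
    for g, grp in df.groupby("group"):
        km = KaplanMeierFitter()
        km.fit(grp["time"], grp["event"], label=str(g))
        curves[g] = km.survival_function_
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return dict(curves=curves, chi_square=float(res.test_statistic),
                df=int(res.degrees_of_freedom), p=float(res.p_value),
                n=len(df), n_events=int(df["event"].sum()))


def _notna(v) -> bool:
    return not (v is None or (isinstance(v, float) and np.isnan(v)))


def cox_workflow(clinical: pd.DataFrame, candidates: Sequence[str],
                 univariate_p_gate: float,
                 censor_horizon: float | None = None) -> dict:
    """Univariate Cox screen, then one multivariate model.

    Each candidate covariate (numeric or categorical — categoricals are
    dummy-coded) is fit alone against (time, event) and its
    likelihood-ratio p recorded; candidates with p below the gate enter
    the multivariate fit.  Returns the univariate table and the
    multivariate hazard-ratio table (HR, 95% CI, p per retained
    covariate term).  Duplicated/collinear covariates are flagged.
    """
    if not 0 < univariate_p_gate < 1:
        raise ValueError("gate must be in (0, 1)")
    df = clinical.copy()
    if censor_horizon is not None:
        over = df["time"] > censor_horizon
        df.loc[over, "event"] = 0
        df.loc[over, "time"] = censor_horizon
    uni_rows = []
    passed = []
    for cov in candidates:
        sub = df[["time", "event", cov]].dropna()
        X = _design(sub, [cov])
        if X.shape[1] == len(["time", "event"]):
            uni_rows.append(dict(covariate=cov, p=np.nan,
                                 note="constant covariate"))
            continue
        cph = CoxPHFitter()
        try:
            cph.fit(X, duration_col="time", event_col="event")
        except ConvergenceError:
            uni_rows.append(dict(covariate=cov, p=np.nan,
                                 note="non-convergent (possible separation)"))
            continue
        p = float(cph.log_likelihood_ratio_test().p_value)
        uni_rows.append(dict(covariate=cov, p=p, note=""))
        if p < univariate_p_gate:
            passed.append(cov)
    univariate = pd.DataFrame(uni_rows)
    result = dict(univariate=univariate, passed=passed,
                  multivariate=None, flags=[])
    if not passed:
        return result
    sub = df[["time", "event", *passed]].dropna()
    X = _design(sub, passed)
    covars = [c for c in X.columns if c not in ("time", "event")]
    corr = X[covars].corr().abs()
    dup = [(a, b) for i, a in enumerate(covars) for b in covars[i + 1:]
           if corr.loc[a, b] > 0.999]
    if dup:
        result["flags"].append(f"collinear covariates: {dup}")
        drop = {b for _, b in dup}
        X = X.drop(columns=list(drop))
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(
            f"multivariate fit failed to converge (covariates {passed}): {exc}"
        ) from exc
    summ = cph.summary
    result["multivariate"] = pd.DataFrame({
        "HR": np.exp(summ["coef"]),
        "ci_low": np.exp(summ["coef lower 95%"]),
        "ci_high": np.exp(summ["coef upper 95%"]),
        "p": summ["p"],
    })
    return result


def _design(sub: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    parts = [sub[["time", "event"]]]
    for cov in covariates:
        col = sub[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(d)
        else:
            if col.nunique() > 1:
                parts.append(col.astype(float))
    return pd.concat(parts, axis=1)
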