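"""Synthetic multi-tumor-type cohorts with known ground truth.

The generator emulates the structure the association framework assumes:
log-normal baseline expression per gene, binary somatic alterations at
set per-tumor-type frequencies, and planted multiplicative shifts of
signature genes (delta, in units of the gene's log-scale standard
deviation) in altered samples of chosen tumor types.  It also draws
survival times from an exponential proportional-hazards model and
per-tumor event orderings from a Plackett-Luce model, so every
downstream stage can be tested against known truth.

All randomness flows from one seed; sub-streams per component are
derived deterministically, so identical (config, seed) gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import AlterationMatrix
from .io_formats import ExpressionMatrix, SignatureSet

import logging

log = logging.getLogger("panhallmark")


@dataclass(frozen=True)
class PlantedEffect:
    signature: str
    delta: float  # shift in within-group SD units on the log scale
    tumor_types: tuple[str, ...]
    sign: int = 1


@dataclass(frozen=True)
class AlterationSpec:
    name: str
    alteration_class: str  # mutation | focal | arm
    frequency: float | Mapping[str, float]
    effects: tuple[PlantedEffect, ...] = ()
    direction: str = "na"

    def freq_for(self, tumor_type: str) -> float:
        if isinstance(self.frequency, Mapping):
            return float(self.frequency.get(tumor_type, 0.0))
        return float(self.frequency)


@dataclass
class CohortConfig:
    n_tumor_types: int = 10
    subtypes_per_type: int = 2
    samples_per_subtype: int = 50
    n_genes: int = 500
    n_signatures: int = 10
    genes_per_signature: int = 20
    signatures: Sequence[SignatureSet] | None = None
    alterations: Sequence[AlterationSpec] = ()
    sigma_range: tuple[float, float] = (0.25, 1.0)
    mu_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tumor_types", "subtypes_per_type",
                     "samples_per_subtype", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def tumor_types(self) -> list[str]:
        return [f"TT{i + 1:02d}" for i in range(self.n_tumor_types)]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    alterations: AlterationMatrix
    truth: tuple[AlterationSpec, ...]
    signatures: tuple[SignatureSet, ...]
    clinical: pd.DataFrame | None = None


def _default_signatures(config: CohortConfig) -> tuple[SignatureSet, ...]:
    """Disjoint gene blocks G0001.., one block per signature."""
    sigs = []
    for k in range(config.n_signatures):
        lo = k * config.genes_per_signature
        hi = lo + config.genes_per_signature
        if hi > config.n_genes:
            raise ValueError("signature blocks exceed the gene universe")
        genes = tuple(f"G{i + 1:04d}" for i in range(lo, hi))
        sigs.append(SignatureSet(f"SIG{k + 1:02d}", genes))
    return tuple(sigs)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort of expression + binary alterations with planted effects.

    Baseline log-expression of gene g is Normal(mu_g, sigma_g) per
    sample (so expression is log-normal); in each altered sample every
    gene of a planted signature is shifted by sign * delta * sigma_g on
    the log scale, i.e. a multiplicative fold change.  Alterations are
    Bernoulli(frequency) independently per sample.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_expr, rng_alt = [np.random.default_rng(s)
                                    for s in ss.spawn(3)]
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    sigs = (tuple(config.signatures) if config.signatures is not None
            else _default_signatures(config))
    sig_by_name = {s.name: s for s in sigs}
    universe = set(genes)
    for s in sigs:
        if not s.gene_set <= universe:
            raise ValueError(f"signature {s.name} has genes outside the universe")
    for spec in config.alterations:
        for eff in spec.effects:
            if eff.signature not in sig_by_name:
                raise ValueError(
                    f"planted signature {eff.signature!r} not in config.signatures")

    mu = rng_genes.uniform(*config.mu_range, size=config.n_genes)
    sigma = rng_genes.uniform(*config.sigma_range, size=config.n_genes)

    samples, ttypes, subtypes = [], [], []
    for t in config.tumor_types:
        for st in range(config.subtypes_per_type):
            for i in range(config.samples_per_subtype):
                samples.append(f"{t}.S{st + 1}.{i + 1:03d}")
                ttypes.append(t)
                subtypes.append(f"{t}_sub{st + 1}")
    n_samples = len(samples)
    ttype_arr = np.array(ttypes)

    logx = mu[:, None] + sigma[:, None] * rng_expr.standard_normal(
        (config.n_genes, n_samples))

    alt_values = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for spec in config.alterations:
        carrier = np.zeros(n_samples, dtype=int)
        for t in config.tumor_types:
            in_t = ttype_arr == t
            f = spec.freq_for(t)
            if f > 0:
                carrier[in_t] = rng_alt.random(in_t.sum()) < f
        alt_values[spec.name] = carrier
        for eff in spec.effects:
            affected = carrier.astype(bool) & np.isin(ttype_arr,
                                                      eff.tumor_types)
            if eff.delta == 0 or not affected.any():
                continue
            pos = [gene_pos[g] for g in sig_by_name[eff.signature].genes]
            shift = np.sign(eff.sign) * eff.delta * sigma[pos]
            logx[np.ix_(pos, affected)] += shift[:, None]

    expr = ExpressionMatrix(
        pd.DataFrame(np.exp(logx), index=pd.Index(genes, name="gene"),
                     columns=samples),
        pd.DataFrame({"tumor_type": ttypes, "subtype": subtypes},
                     index=pd.Index(samples, name="sample")),
    )
    if alt_values:
        values = pd.DataFrame(alt_values, index=pd.Index(samples, name="sample"))
        meta = pd.DataFrame({
            "alteration_class": [s.alteration_class for s in config.alterations],
            "direction": [s.direction for s in config.alterations],
            "qualifying_types": [
                tuple(t for t in config.tumor_types if s.freq_for(t) > 0)
                for s in config.alterations],
        }, index=[s.name for s in config.alterations])
        alts = AlterationMatrix(values, meta)
    else:
        alts = AlterationMatrix(
            pd.DataFrame(index=pd.Index(samples, name="sample")),
            pd.DataFrame(columns=["alteration_class", "direction",
                                  "qualifying_types"]))
    return SyntheticCohort(expr, alts, tuple(config.alterations), sigs)


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write a cohort in the formats the io layer reads.

    expression.tsv (genes x samples), labels.tsv (sample, tumor_type,
    subtype), mutations.maf (one nonsynonymous row per carrier of each
    mutation-class alteration), alterations.tsv (binary matrix),
    signatures.gmt, and clinical.tsv when present — so the shell
    pipeline runs on synthetic data unchanged.
    """
    import os

    from .io_formats import (MutationTable, write_expression_matrix,
                             write_gmt, write_maf, write_tsv)

    os.makedirs(directory, exist_ok=True)
    write_expression_matrix(cohort.expression,
                            os.path.join(directory, "expression.tsv"))
    write_tsv(cohort.expression.sample_labels,
              os.path.join(directory, "labels.tsv"))
    write_gmt(cohort.signatures, os.path.join(directory, "signatures.gmt"))
    write_tsv(cohort.alterations.values,
              os.path.join(directory, "alterations.tsv"))
    mut_cols = cohort.alterations.meta.index[
        cohort.alterations.meta["alteration_class"] == "mutation"]
    rows = []
    for alt in mut_cols:
        carriers = cohort.alterations.values.index[
            cohort.alterations.values[alt] == 1]
        rows += [dict(sample=s, gene=alt,
                      variant_classification="Missense_Mutation",
                      is_hotspot=False) for s in carriers]
    if rows:
        write_maf(MutationTable(pd.DataFrame(rows)),
                  os.path.join(directory, "mutations.maf"))
    if cohort.clinical is not None:
        write_tsv(cohort.clinical, os.path.join(directory, "clinical.tsv"))


def generate_event_orderings(worths: Mapping[str, float], n_tumors: int,
                             missing_rate: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Per-tumor rankings of somatic events drawn from a Plackett-Luce model.

    Each tumor observes every event independently with probability
    1 - missing_rate; its ranking over observed events is drawn
    sequentially with selection probability proportional to worth.
    Returns a long table (tumor, event, rank, ccf) with CCF values
    assigned consistently with the drawn order (evenly spaced from 1.0
    downward).  Tumors left with fewer than 2 events are omitted with a
    warning.
    """
    events = list(worths)
    if len(events) < 2:
        raise ValueError("need >= 2 events")
    w = np.array([worths[e] for e in events], dtype=float)
    if (w <= 0).any():
        raise ValueError("worths must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for t in range(n_tumors):
        present = np.flatnonzero(rng.random(len(events)) >= missing_rate)
        if present.size < 2:
            n_dropped += 1
            continue
        remaining = list(present)
        order = []
        while remaining:
            pw = w[remaining]
            pick = rng.choice(len(remaining), p=pw / pw.sum())
            order.append(remaining.pop(pick))
        k = len(order)
        ccfs = np.linspace(1.0, 1.0 / k, k) if k > 1 else np.array([1.0])
        for rank, (ev, ccf) in enumerate(zip(order, ccfs), start=1):
            rows.append(dict(tumor=f"T{t + 1:04d}", event=events[ev],
                             rank=rank, ccf=float(ccf)))
    if n_dropped:
        log.warning("%d tumors omitted (<2 observed events)", n_dropped)
    return pd.DataFrame(rows)


def generate_survival(covariates: pd.DataFrame,
                      log_hazard_ratios: Mapping[str, float],
                      baseline_rate: float = 0.1,
                      censor_horizon: float = 10.0,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival times under a proportional-hazards model.

    hazard_i = baseline_rate * exp(sum_k beta_k x_ik); administrative
    censoring at ``censor_horizon`` years.  Returns a clinical table
    (index sample; time, event, plus the covariates).
    """
    lin = np.zeros(len(covariates))
    for cov, beta in log_hazard_ratios.items():
        lin = lin + beta * covariates[cov].values.astype(float)
    if not np.isfinite(lin).all():
        raise ValueError("non-finite linear predictor")
    rng = np.random.default_rng(seed)
    hazard = baseline_rate * np.exp(lin)
    times = rng.exponential(1.0 / hazard)
    event = (times <= censor_horizon).astype(int)
    times = np.minimum(times, censor_horizon)
    out = covariates.copy()
    out.insert(0, "event", event)
    out.insert(0, "time", times)
    return out
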