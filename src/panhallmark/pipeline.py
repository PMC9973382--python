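"""End-to-end orchestration: simulate -> score -> associate -> adjust ->
cluster -> timing -> survive, from one config with one seed.

Every output TSV carries a provenance header (config hash, seed, stage)
and reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (count_directional, permutation_consistency_fdr,
                    subtype_adjusted_glm, adjust_glm_records, wilcoxon_scan)
from .cluster import cluster_marker_test, hierarchical_cut, subtype_mean_matrix
from .io_formats import write_tsv
from .sigscore import ssgsea_scores
from .survival import binarize_by_quartile, cox_workflow, km_logrank
from .synthdata import (AlterationSpec, CohortConfig, PlantedEffect,
                        generate_cohort, generate_event_orderings,
                        generate_survival)
from .timing import bootstrap_timing_ci, build_rankings, fit_plackett_luce

log = logging.getLogger("panhallmark")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, pre-filled with the standard defaults.

    Scan p thresholds 1e-3 (mutation, focal) / 1e-7 (arm); FDR display
    1e-4 / 1e-4 / 1e-7; dendrogram cut heights 0.70 (sample-level
    signatures), 1.6 (subtype signatures), 1.1 (subtype CNAs);
    aneuploidy high cut 15; survival censoring at 10 years.
    """

    out_dir: str = "results"
    seed: int = 7
    # synthetic cohort
    n_tumor_types: int = 6
    subtypes_per_type: int = 2
    samples_per_subtype: int = 40
    n_genes: int = 400
    n_signatures: int = 8
    genes_per_signature: int = 20
    n_alterations: int = 8
    alteration_frequency: float = 0.3
    planted_delta: float = 1.0
    planted_fraction_of_types: float = 0.5
    # scoring
    ssgsea_weight: float = 0.75
    min_overlap: int = 5
    normalization: str = "raw"
    # association
    p_threshold_mutation: float = 1e-3
    p_threshold_focal: float = 1e-3
    p_threshold_arm: float = 1e-7
    fdr_display_mutation: float = 1e-4
    fdr_display_focal: float = 1e-4
    fdr_display_arm: float = 1e-7
    n_perm: int = 10_000
    # clustering
    cut_height_subtype: float = 1.6
    cut_height_cna: float = 1.1
    linkage: str = "wardD2"
    min_type_n: int = 50
    min_subtype_n: int = 10
    marker_n_perm: int = 1000
    marker_q_display: float = 1e-4
    # timing
    timing_worths: tuple = (8.0, 4.0, 2.0, 1.0)
    timing_n_tumors: int = 100
    timing_missing_rate: float = 0.2
    timing_B: int = 200
    timing_epsilon: float = 0.1
    # survival
    aneuploidy_high_cut: int = 15
    censor_years: float = 10.0
    univariate_gate: float = 0.2
    survival_log_hr: float = 0.6931471805599453  # log 2
    # stage toggles
    stages: tuple = ("simulate", "score", "associate", "adjust", "cluster",
                     "timing", "survive")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where results land does not change what they are
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_STAGE_DEPS = {
    "score": ("simulate",),
    "associate": ("score",),
    "adjust": ("score",),
    "cluster": ("score",),
    "survive": ("score",),
    "timing": (),
    "simulate": (),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the results.

    Raises if an enabled stage's upstream stage is disabled.  All TSV
    outputs land in ``config.out_dir`` with a provenance header.
    """
    enabled = list(config.stages)
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise ValueError(f"stage {stage!r} requires {dep!r}")
    os.makedirs(config.out_dir, exist_ok=True)
    stamp = (f"panhallmark v{__version__} config={config.config_hash()} "
             f"seed={config.seed}")
    results: dict = {}

    def emit(name, df, index=True):
        write_tsv(df, os.path.join(config.out_dir, f"{name}.tsv"),
                  index=index, header_comment=f"{stamp} stage={name}")

    if "simulate" in enabled:
        cohort = _simulate(config)
        results["cohort"] = cohort
        emit("alterations", cohort.alterations.values)
        emit("sample_labels", cohort.expression.sample_labels)

    if "score" in enabled:
        cohort = results["cohort"]
        scores = ssgsea_scores(cohort.expression, cohort.signatures,
                               weight=config.ssgsea_weight,
                               min_overlap=config.min_overlap,
                               normalize=config.normalization,
                               seed=config.seed)
        results["scores"] = scores
        emit("signature_scores", scores.scores)

    type_labels = subtype_labels = None
    if "simulate" in enabled:
        lbl = results["cohort"].expression.sample_labels
        type_labels = lbl["tumor_type"].to_dict()
        subtype_labels = lbl["subtype"].to_dict()

    if "associate" in enabled:
        cohort, scores = results["cohort"], results["scores"]
        scan = wilcoxon_scan(scores, cohort.alterations, type_labels)
        results["scan"] = scan
        emit("wilcoxon_scan", scan, index=False)
        counts = count_directional(scan, config.p_threshold_mutation)
        results["counts"] = counts
        emit("directional_counts", counts, index=False)
        cands = counts[counts["candidate"]]
        records = permutation_consistency_fdr(
            scores, cohort.alterations, cands, type_labels,
            n_perm=config.n_perm,
            p_threshold={"mutation": config.p_threshold_mutation,
                         "focal": config.p_threshold_focal,
                         "arm": config.p_threshold_arm},
            seed=config.seed)
        results["associations"] = records
        emit("associations", records, index=False)

    if "adjust" in enabled:
        cohort, scores = results["cohort"], results["scores"]
        parts = []
        for t in sorted(set(type_labels.values())):
            parts.append(subtype_adjusted_glm(
                scores, cohort.alterations, subtype_labels, type_labels, t))
        glm = adjust_glm_records(pd.concat(parts, ignore_index=True))
        results["glm"] = glm
        emit("subtype_adjusted_glm", glm, index=False)

    if "cluster" in enabled:
        scores = results["scores"]
        sm = subtype_mean_matrix(scores, type_labels, subtype_labels,
                                 min_type_n=config.min_type_n,
                                 min_subtype_n=config.min_subtype_n)
        assign = hierarchical_cut(sm, config.cut_height_subtype,
                                  linkage=config.linkage)
        results["clusters"] = assign
        emit("subtype_clusters", assign.labels.to_frame())
        emit("dendrogram", assign.merges, index=False)
        sample_cluster = {
            s: int(assign.labels[subtype_labels[s]])
            for s in scores.scores.columns
            if subtype_labels[s] in assign.labels.index}
        markers = cluster_marker_test(scores.scores, sample_cluster,
                                      n_perm=config.marker_n_perm,
                                      q_display=config.marker_q_display,
                                      seed=config.seed)
        results["markers"] = markers
        emit("cluster_markers", markers, index=False)

    if "timing" in enabled:
        worths = {f"event{i + 1}": w
                  for i, w in enumerate(config.timing_worths)}
        orderings = generate_event_orderings(
            worths, config.timing_n_tumors,
            missing_rate=config.timing_missing_rate, seed=config.seed)
        rankings = build_rankings(orderings[["tumor", "event", "ccf"]])
        fit = fit_plackett_luce(rankings, epsilon=config.timing_epsilon,
                                seed=config.seed)
        ci = bootstrap_timing_ci(rankings, B=config.timing_B,
                                 seed=config.seed,
                                 epsilon=config.timing_epsilon)
        results["timing"] = dict(truth=worths, fit=fit, ci=ci)
        emit("timing_worths", fit.worths.to_frame())
        emit("timing_ci", ci)

    if "survive" in enabled:
        cohort, scores = results["cohort"], results["scores"]
        sig = scores.scores.index[0]
        high = binarize_by_quartile(scores, sig, type_labels,
                                    grouping="per-type")
        cov = pd.DataFrame({"signature_high": high})
        clinical = generate_survival(
            cov, {"signature_high": config.survival_log_hr},
            censor_horizon=config.censor_years, seed=config.seed)
        results["clinical"] = clinical
        km = km_logrank(clinical, high.to_dict(),
                        censor_horizon=config.censor_years)
        results["km"] = km
        emit("logrank", pd.DataFrame([{k: km[k] for k in
                                       ("chi_square", "df", "p", "n",
                                        "n_events")}]), index=False)
        cox = cox_workflow(clinical, ["signature_high"],
                           config.univariate_gate,
                           censor_horizon=config.censor_years)
        results["cox"] = cox
        if cox["multivariate"] is not None:
            emit("cox_multivariate", cox["multivariate"])
        emit("cox_univariate", cox["univariate"], index=False)
    return results


def _simulate(config: PipelineConfig):
    types = [f"TT{i + 1:02d}" for i in range(config.n_tumor_types)]
    n_affected = max(1, int(round(config.planted_fraction_of_types
                                  * config.n_tumor_types)))
    alterations = []
    for k in range(config.n_alterations):
        effects = ()
        if k == 0:  # one planted driver-like alteration; the rest are null
            effects = (PlantedEffect(signature="SIG01",
                                     delta=config.planted_delta,
                                     tumor_types=tuple(types[:n_affected]),
                                     sign=1),)
        alterations.append(AlterationSpec(
            name=f"ALT{k + 1:02d}", alteration_class="mutation",
            frequency=config.alteration_frequency, effects=effects))
    cc = CohortConfig(n_tumor_types=config.n_tumor_types,
                      subtypes_per_type=config.subtypes_per_type,
                      samples_per_subtype=config.samples_per_subtype,
                      n_genes=config.n_genes,
                      n_signatures=config.n_signatures,
                      genes_per_signature=config.genes_per_signature,
                      alterations=alterations, seed=config.seed)
    return generate_cohort(cc)
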