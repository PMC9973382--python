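"""Curation of somatic alterations into a binary alteration matrix.

Mutations are classified synonymous/nonsynonymous and nominated as
drivers per group (tumor subtype and tumor type) with an outlier rule
(count strictly above Q3 + 3*IQR of the group's per-gene nonsynonymous
counts), a minimum of three mutated tumors, and — for tumor
suppressors — a silent-mutation fraction below 20%.  Focal CNAs are
filtered by GISTIC q-value and peak width and collapsed over any-base
overlap; arm calls are expanded into binary Amp/Del columns;
aneuploidy, whole-genome-doubling and segment-based arm-fraction calls
round out the copy-number side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import quantile
from .io_formats import (ARM_IDS, ArmCallMatrix, GisticResult, MutationTable,
                         SegmentTable, SYNONYMOUS_CLASSES)

log = logging.getLogger("panhallmark")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AlterationMatrix:
    """Samples x alterations binary matrix with per-alteration metadata.

    ``meta`` is indexed by alteration id and carries ``alteration_class``
    (mutation | focal | arm), ``direction`` (amp | del | na) and
    ``qualifying_types`` (tuple of tumor types in which the alteration
    passed curation).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        v = self.values
        vals = v.values.astype(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0))
        if not ok.all():
            raise ValueError("alteration values must be binary (or missing)")
        missing_meta = [a for a in v.columns if a not in self.meta.index]
        if missing_meta:
            raise ValueError(f"alterations without metadata: {missing_meta[:5]}")
        if self.meta["qualifying_types"].map(len).eq(0).any():
            raise ValueError("every alteration must list >=1 qualifying tumor type")
        # arm alterations come in Amp/Del column pairs, never both 1
        arm_cols = self.meta.index[self.meta["alteration_class"] == "arm"]
        bases = {}
        for col in arm_cols:
            base = col.rsplit("_", 1)[0]
            bases.setdefault(base, []).append(col)
        for base, cols in bases.items():
            if len(cols) == 2:
                both = (v[cols[0]] == 1) & (v[cols[1]] == 1)
                if both.any():
                    raise ValueError(f"arm {base}: sample amplified AND deleted")

    def subset(self, alterations: Sequence[str]) -> "AlterationMatrix":
        return AlterationMatrix(self.values[list(alterations)],
                                self.meta.loc[list(alterations)])


@dataclass
class DriverCatalog:
    """Per gene-group curation decisions plus the resulting gene-type combos."""

    table: pd.DataFrame  # gene, group, level, counts, threshold, passed, reason
    combos: pd.DataFrame  # gene, tumor_type pairs (union over levels)

    @property
    def passing_genes(self) -> set:
        return set(self.combos["gene"])


@dataclass
class AneuploidyProfile:
    """Arm-level alteration burden of one sample."""

    sample: str
    score: int
    high: bool
    wgd: bool | None = None
    ploidy: float | None = None


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------


def classify_variant(variant_classification: str) -> str:
    """Classify a MAF term as 'synonymous' or 'nonsynonymous'.

    Terms outside the synonymous list (including unknown ones) are
    nonsynonymous by the rule.
    """
    if not variant_classification:
        raise ValueError("empty variant classification")
    if variant_classification in SYNONYMOUS_CLASSES:
        return "synonymous"
    return "nonsynonymous"


def outlier_threshold(counts: Sequence[float]) -> float:
    """Q3 + 3*IQR of a list of counts (linear-interpolation quantiles)."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("outlier_threshold of empty counts")
    q1 = quantile(counts, 0.25)
    q3 = quantile(counts, 0.75)
    return q3 + 3.0 * (q3 - q1)


def _per_group_counts(df: pd.DataFrame, groups: Mapping[str, str],
                      genes: Sequence[str]):
    """Distinct mutated-tumor counts per (group, gene), plus silent fractions."""
    df = df.assign(group=df["sample"].map(groups))
    df = df[df["group"].notna()]
    df = df.assign(kind=df["variant_classification"].map(classify_variant))
    out = {}
    for group, gdf in df.groupby("group", sort=True):
        nonsyn = (gdf[gdf["kind"] == "nonsynonymous"]
                  .groupby("gene")["sample"].nunique())
        counts = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=float)
        counts.update(nonsyn[nonsyn.index.isin(genes)])
        total = gdf.groupby("gene").size()
        silent = gdf[gdf["kind"] == "synonymous"].groupby("gene").size()
        out[group] = (counts, total, silent)
    return out


def _run_driver_filter(muts: MutationTable, groups: Mapping[str, str],
                       gene_list: set, group_to_type: Mapping[str, str],
                       level: str, silent_rule: bool,
                       hotspot_only: bool) -> pd.DataFrame:
    df = muts.df
    if hotspot_only:
        df = df[df["is_hotspot"].astype(bool)]
    df = df[df["gene"].isin(gene_list)]
    genes = sorted(gene_list)
    rows = []
    for group, (counts, total, silent) in _per_group_counts(
            df, groups, genes).items():
        thr = outlier_threshold(counts.values)
        for gene in genes:
            c = counts[gene]
            n_total = int(total.get(gene, 0))
            n_silent = int(silent.get(gene, 0))
            frac_silent = n_silent / n_total if n_total else 0.0
            reasons = []
            if not c > thr:
                reasons.append("not above outlier threshold")
            if c < 3:
                reasons.append("fewer than 3 mutated tumors")
            if silent_rule and not frac_silent < 0.20:
                reasons.append("silent fraction >= 20%")
            rows.append(dict(gene=gene, group=group, level=level,
                             tumor_type=group_to_type.get(group, group),
                             n_mutated=c, n_total=n_total, n_silent=n_silent,
                             silent_fraction=frac_silent, threshold=thr,
                             passed=not reasons,
                             reason=";".join(reasons) if reasons else "pass"))
    return pd.DataFrame(rows)


def _select_drivers(muts, sample_types, sample_subtypes, gene_list,
                    silent_rule, hotspot_only) -> DriverCatalog:
    gene_list = set(gene_list)
    parts = [_run_driver_filter(muts, dict(sample_types), gene_list,
                                {}, "tumor_type", silent_rule, hotspot_only)]
    if sample_subtypes:
        sub_to_type = {}
        for s, sub in sample_subtypes.items():
            if sub is not None and not (isinstance(sub, float) and np.isnan(sub)):
                sub_to_type[sub] = sample_types[s]
        subs = {s: v for s, v in sample_subtypes.items()
                if v is not None and not (isinstance(v, float) and np.isnan(v))}
        parts.append(_run_driver_filter(muts, subs, gene_list, sub_to_type,
                                        "subtype", silent_rule, hotspot_only))
    table = pd.concat(parts, ignore_index=True)
    combos = (table[table["passed"]][["gene", "tumor_type"]]
              .drop_duplicates().sort_values(["gene", "tumor_type"])
              .reset_index(drop=True))
    return DriverCatalog(table, combos)


def select_tumor_suppressors(muts: MutationTable,
                             sample_types: Mapping[str, str],
                             tsg_list: Sequence[str],
                             sample_subtypes: Mapping[str, str] | None = None,
                             ) -> DriverCatalog:
    """Nominate tumor suppressors per tumor type (and subtype, if given).

    A gene passes in a group iff its count of nonsynonymously mutated
    tumors is strictly above the group's Q3 + 3*IQR threshold (computed
    over the supplied gene list), at least 3, and its silent-mutation
    fraction is below 20%.  Subtype- and type-level passes are unioned
    into gene-tumor-type combinations.
    """
    return _select_drivers(muts, sample_types, sample_subtypes, tsg_list,
                           silent_rule=True, hotspot_only=False)


def select_oncogenes(muts: MutationTable,
                     sample_types: Mapping[str, str],
                     oncogene_list: Sequence[str],
                     sample_subtypes: Mapping[str, str] | None = None,
                     ) -> DriverCatalog:
    """As select_tumor_suppressors but on hotspot mutations only, without
    the silent-fraction rule."""
    return _select_drivers(muts, sample_types, sample_subtypes, oncogene_list,
                           silent_rule=False, hotspot_only=True)


def mutation_matrix(muts: MutationTable, catalog: DriverCatalog,
                    sample_types: Mapping[str, str],
                    samples: Sequence[str]) -> AlterationMatrix:
    """Binary sample x gene-mutation matrix restricted to curated genes."""
    df = muts.df
    df = df[df["variant_classification"].map(classify_variant) == "nonsynonymous"]
    qualifying = catalog.combos.groupby("gene")["tumor_type"].agg(tuple)
    values = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                          columns=[f"{g}_Mut" for g in qualifying.index])
    for gene, col in zip(qualifying.index, values.columns):
        carriers = df.loc[df["gene"] == gene, "sample"].unique()
        values.loc[values.index.isin(carriers), col] = 1
    meta = pd.DataFrame({
        "alteration_class": "mutation",
        "direction": "na",
        "qualifying_types": [qualifying[g] for g in qualifying.index],
    }, index=values.columns)
    return AlterationMatrix(values, meta)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


def filter_focal_peaks(gistic: GisticResult, q_max: float = 0.01,
                       min_width: int = 250_000,
                       gene_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Filter GISTIC focal peaks by q and width, merge overlaps, map genes.

    Surviving peaks (q <= q_max, width >= min_width) are merged within a
    chromosome and direction whenever any base overlaps (transitively);
    merged intervals get the nearest gene from ``gene_map`` (BED-like
    columns chromosome, start, end, gene) or a coordinate-derived id.
    """
    fp = gistic.focal_peaks.copy()
    fp = fp[(fp["q_value"] <= q_max) & ((fp["end"] - fp["start"]) >= min_width)]
    merged_rows = []
    for (chrom, direction), grp in fp.groupby(["chromosome", "direction"],
                                              sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for _, row in grp.iterrows():
            if cur_s is None:
                cur_s, cur_e = row["start"], row["end"]
            elif row["start"] <= cur_e:  # any-base overlap (closed intervals)
                cur_e = max(cur_e, row["end"])
            else:
                merged_rows.append((chrom, cur_s, cur_e, direction))
                cur_s, cur_e = row["start"], row["end"]
        if cur_s is not None:
            merged_rows.append((chrom, cur_s, cur_e, direction))
    out = pd.DataFrame(merged_rows,
                       columns=["chromosome", "start", "end", "direction"])
    names = []
    for _, row in out.iterrows():
        name = _nearest_gene(row, gene_map)
        if name is None:
            name = f"{row['chromosome']}:{row['start']}-{row['end']}"
            log.warning("focal peak %s has no mappable gene; keeping interval id",
                        name)
        names.append(f"{name}_{'Amp' if row['direction'] == 'amp' else 'Del'}")
    out["alteration"] = names
    return out.reset_index(drop=True)


def _nearest_gene(peak, gene_map: pd.DataFrame | None):
    if gene_map is None or gene_map.empty:
        return None
    gm = gene_map[gene_map["chromosome"] == peak["chromosome"]]
    if gm.empty:
        return None
    # distance 0 on overlap, else gap between interval ends
    dist = np.maximum(gm["start"] - peak["end"], 0) + np.maximum(
        peak["start"] - gm["end"], 0)
    return gm.loc[dist.idxmin(), "gene"]


def binarize_arm_calls(calls: ArmCallMatrix,
                       qualifying_types: Mapping[str, Sequence[str]] | None = None,
                       sample_types: Mapping[str, str] | None = None,
                       ) -> AlterationMatrix:
    """Expand each arm into binary Amp/Del columns.

    +1 -> (1, 0); -1 -> (0, 1); 0 -> (0, 0); missing -> missing in both.
    ``qualifying_types`` optionally restricts per-alteration qualifying
    tumor types; by default every tumor type present qualifies.
    """
    cols = {}
    for arm in calls.calls.columns:
        c = calls.calls[arm]
        cols[f"{arm}_Amp"] = (c == 1).astype(float).where(c.notna())
        cols[f"{arm}_Del"] = (c == -1).astype(float).where(c.notna())
    values = pd.DataFrame(cols, index=calls.calls.index)
    if qualifying_types is None:
        if sample_types is not None:
            all_types = tuple(sorted(set(sample_types.values())))
        else:
            all_types = ("all",)
        qualifying_types = {a: all_types for a in values.columns}
    meta = pd.DataFrame({
        "alteration_class": "arm",
        "direction": ["amp" if a.endswith("_Amp") else "del"
                      for a in values.columns],
        "qualifying_types": [tuple(qualifying_types[a]) for a in values.columns],
    }, index=values.columns)
    return AlterationMatrix(values, meta)


def aneuploidy_profile(binary_arms: AlterationMatrix,
                       ploidy: Mapping[str, float] | None = None,
                       high_cut: int = 15,
                       wgd_ploidy: float = 3.0) -> list[AneuploidyProfile]:
    """Aneuploidy score = number of arms altered; high iff score > 15;
    WGD iff average ploidy >= 3 (when ploidy is supplied)."""
    profiles = []
    v = binary_arms.values
    for sample in v.index:
        row = v.loc[sample]
        if row.isna().any():
            log.warning("sample %s has missing arm calls; aneuploidy over "
                        "observed arms only", sample)
        score = int(row.fillna(0).sum())
        p = None if ploidy is None else ploidy.get(sample)
        wgd = None if p is None else bool(p >= wgd_ploidy)
        profiles.append(AneuploidyProfile(sample=sample, score=score,
                                          high=score > high_cut, wgd=wgd,
                                          ploidy=p))
    return profiles


def arm_fraction_calls(segs: SegmentTable,
                       arm_definitions: Mapping[str, tuple],
                       seg_threshold: float = 0.1,
                       arm_fraction: float = 0.5) -> ArmCallMatrix:
    """Call arm-level CNAs from segments by altered-base fraction.

    A segment is amplified if log2 ratio > seg_threshold, deleted if
    < -seg_threshold.  An arm is amplified (deleted) iff the amplified
    (deleted) base fraction of the arm exceeds ``arm_fraction``; if both
    directions exceed, the call is neutral with a warning.  Arms with no
    covering segment are missing.
    """
    samples = sorted(segs.df["sample"].unique())
    arms = list(arm_definitions)
    calls = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample"),
                         columns=arms)
    for sample, sdf in segs.df.groupby("sample"):
        for arm, (chrom, a_start, a_end) in arm_definitions.items():
            arm_len = a_end - a_start
            if arm_len <= 0:
                continue
            seg = sdf[sdf["chromosome"] == chrom]
            ov_start = np.maximum(seg["start"].values, a_start)
            ov_end = np.minimum(seg["end"].values, a_end)
            ov = np.maximum(ov_end - ov_start, 0)
            if ov.sum() == 0:
                continue  # stays missing
            lr = seg["log2_ratio"].values
            amp_frac = ov[lr > seg_threshold].sum() / arm_len
            del_frac = ov[lr < -seg_threshold].sum() / arm_len
            if amp_frac > arm_fraction and del_frac > arm_fraction:
                log.warning("sample %s arm %s: both directions exceed %.0f%%; "
                            "neutral", sample, arm, 100 * arm_fraction)
                calls.loc[sample, arm] = 0
            elif amp_frac > arm_fraction:
                calls.loc[sample, arm] = 1
            elif del_frac > arm_fraction:
                calls.loc[sample, arm] = -1
            else:
                calls.loc[sample, arm] = 0
    valid_arms = [a for a in arms if a in ARM_IDS]
    if len(valid_arms) == len(arms):
        return ArmCallMatrix(calls)
    # non-canonical arm ids (e.g. mouse chromosomes) bypass the 39-arm check
    obj = ArmCallMatrix.__new__(ArmCallMatrix)
    obj.calls, obj.ploidy, obj.aneuploidy_score = calls, None, None
    return obj


def subtype_cna_matrix(binary_arms: AlterationMatrix,
                       subtype_labels: Mapping[str, str]) -> pd.DataFrame:
    """Arms x subtypes matrix of signed alteration percentages.

    Per subtype and arm, the larger of %amplified and %deleted is kept;
    deletions carry a minus sign; ties resolve to amplification.
    """
    v = binary_arms.values
    sub = pd.Series({s: subtype_labels[s] for s in v.index})
    arms = sorted({a.rsplit("_", 1)[0] for a in v.columns})
    out = {}
    for subtype, samples in sub.groupby(sub):
        idx = samples.index
        col = {}
        for arm in arms:
            amp = 100.0 * v.loc[idx, f"{arm}_Amp"].mean()
            dele = 100.0 * v.loc[idx, f"{arm}_Del"].mean()
            col[arm] = amp if amp >= dele else -dele
        out[subtype] = col
    return pd.DataFrame(out).loc[arms]


def focal_arm_cooccurrence(focal: AlterationMatrix, arms: AlterationMatrix,
                           focal_to_arm: Mapping[str, str],
                           sample_types: Mapping[str, str]) -> pd.DataFrame:
    """Percent of focal-event carriers also carrying the same-direction arm event.

    One row per focal alteration and tumor type; ``focal_to_arm`` maps a
    focal alteration id to its host arm alteration id (same direction).
    """
    rows = []
    types = pd.Series({s: sample_types[s] for s in focal.values.index})
    for falt in focal.values.columns:
        if falt not in focal_to_arm:
            raise ValueError(f"focal alteration {falt!r} has no arm mapping")
        aalt = focal_to_arm[falt]
        for ttype, samples in types.groupby(types):
            idx = samples.index
            carriers = focal.values.loc[idx, falt] == 1
            n = int(carriers.sum())
            if n == 0:
                continue
            both = (arms.values.loc[idx, aalt][carriers] == 1).sum()
            rows.append(dict(focal=falt, arm=aalt, tumor_type=ttype,
                             n_focal=n, pct_cooccur=100.0 * both / n))
    return pd.DataFrame(rows)
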