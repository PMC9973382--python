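"""Readers and writers for the tabular formats the pipeline touches.

GMT gene-set collections (MSigDB dialect), genes x samples expression
TSV, MAF-style mutation tables (MC3 column names), per-sample arm-call
matrices, GISTIC-style focal/broad result tables, SEG segmentation
files and clinical tables.  All tabular output is TSV with a header;
floats are serialized with 12 significant digits so reruns are
byte-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("panhallmark")

FLOAT_FORMAT = "%.12g"

#: canonical 39 autosomal chromosome arms (acrocentric p-arms excluded)
ARM_IDS: tuple[str, ...] = tuple(
    f"{c}{a}"
    for c in range(1, 23)
    for a in ("p", "q")
    if not (a == "p" and c in (13, 14, 15, 21, 22))
)

#: MAF variant classifications counted as synonymous
SYNONYMOUS_CLASSES = frozenset(
    {"3'Flank", "3'UTR", "5'Flank", "5'UTR", "Intron", "RNA", "Silent"}
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureSet:
    """A named gene set: the unit of single-sample scoring."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression with optional sample labels.

    ``sample_labels`` maps sample id -> (tumor_type, subtype); subtype may
    be missing (NaN), tumor_type must be present for every labelled sample.
    """

    values: pd.DataFrame
    sample_labels: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (v.values < 0).any():
            raise ValueError("negative expression values")
        if self.sample_labels is not None:
            lbl = self.sample_labels
            missing = [s for s in v.columns if s not in lbl.index]
            if missing:
                raise ValueError(f"samples without labels: {missing[:5]}")
            if lbl.loc[list(v.columns), "tumor_type"].isna().any():
                raise ValueError("every sample needs a tumor_type label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_labels(self, labels: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values, labels)

    def tumor_type_of(self) -> pd.Series:
        if self.sample_labels is None:
            raise ValueError("no sample labels attached")
        return self.sample_labels.loc[list(self.values.columns), "tumor_type"]


@dataclass
class MutationTable:
    """Rows of (sample, gene, variant_classification, is_hotspot, protein_change)."""

    df: pd.DataFrame

    REQUIRED = ("sample", "gene", "variant_classification")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"missing column {col!r}")
        if "is_hotspot" not in self.df.columns:
            self.df = self.df.assign(is_hotspot=False)

    def __len__(self):
        return len(self.df)


@dataclass
class ArmCallMatrix:
    """Samples x chromosome arms, values in {-1, 0, +1, NaN}."""

    calls: pd.DataFrame
    ploidy: pd.Series | None = None
    aneuploidy_score: pd.Series | None = None

    def __post_init__(self):
        bad = [c for c in self.calls.columns if c not in ARM_IDS]
        if bad:
            raise ValueError(
                f"unknown arm column(s) {bad}; valid arm ids: {list(ARM_IDS)}"
            )
        vals = self.calls.values.astype(float)
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("arm calls restricted to {-1, 0, 1, missing}")


@dataclass
class GisticResult:
    """Parsed GISTIC-style output: focal peaks and broad arm calls."""

    focal_peaks: pd.DataFrame  # peak_id, chromosome, start, end, direction, q_value, gene
    broad_arms: pd.DataFrame  # arm, direction, q_value

    def __post_init__(self):
        fp = self.focal_peaks
        if len(fp):
            if (fp["start"] >= fp["end"]).any():
                raise ValueError("focal peak with end <= start")
            if ((fp["q_value"] < 0) | (fp["q_value"] > 1)).any():
                raise ValueError("q_value outside [0, 1]")
            if not fp["direction"].isin(["amp", "del"]).all():
                raise ValueError("direction must be 'amp' or 'del'")
        ba = self.broad_arms
        if len(ba) and not ba["direction"].isin(["amp", "del"]).all():
            raise ValueError("direction must be 'amp' or 'del'")


@dataclass
class SegmentTable:
    """Copy-number segments: (sample, chromosome, start, end, log2_ratio)."""

    df: pd.DataFrame

    def __post_init__(self):
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("segment with end <= start")
        for (_, _), grp in self.df.groupby(["sample", "chromosome"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError("overlapping segments within a sample/chromosome")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[SignatureSet]:
    """Parse an MSigDB-style GMT file into a list of signature sets."""
    sets: list[SignatureSet] = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict = {}
            for g in genes:
                seen.setdefault(g, None)
            if name in names:
                raise ParseError(f"{path}: duplicate signature name {name!r}")
            names.add(name)
            sets.append(SignatureSet(name, tuple(seen), desc))
    if not sets:
        raise ParseError(f"{path}: no signatures")
    return sets


def write_gmt(sets: Iterable[SignatureSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_expression_matrix(path, gene_filter: Iterable[str] | None = None,
                           collapse: str = "median") -> ExpressionMatrix:
    """Read a genes x samples TSV; optionally keep only ``gene_filter`` genes.

    Duplicate gene rows are collapsed to one row by ``collapse`` (median
    per sample by default).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.values.argmax()]
                raise ParseError(
                    f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    if gene_filter is not None:
        keep = df.index.isin(set(gene_filter))
        df = df.loc[keep]
        if df.empty:
            raise ParseError(f"{path}: no genes survive the gene filter")
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).agg(collapse)
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                       index_label="gene")


def read_sample_labels(path) -> pd.DataFrame:
    """Sample -> (tumor_type, subtype) table; first column is the sample id."""
    lbl = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "tumor_type" not in lbl.columns:
        raise ParseError(f"{path}: missing column 'tumor_type'")
    if "subtype" not in lbl.columns:
        lbl["subtype"] = np.nan
    return lbl


_MAF_COLS = {
    "Hugo_Symbol": "gene",
    "Tumor_Sample_Barcode": "sample",
    "Variant_Classification": "variant_classification",
    "HGVSp_Short": "protein_change",
    "is_hotspot": "is_hotspot",
}


def read_maf(path) -> MutationTable:
    """Read a MAF-style mutation table (MC3 column names).

    Variant classification strings are kept verbatim; classification into
    synonymous/nonsynonymous happens downstream in curation.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for req in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if req not in df.columns:
            raise ParseError(f"{path}: missing required column {req!r}")
    out = pd.DataFrame(
        {new: df[old] for old, new in _MAF_COLS.items() if old in df.columns}
    )
    if "is_hotspot" in out.columns:
        out["is_hotspot"] = out["is_hotspot"].isin(["True", "TRUE", "1", "true"])
    return MutationTable(out.reset_index(drop=True))


def write_maf(muts: MutationTable, path) -> None:
    inv = {v: k for k, v in _MAF_COLS.items()}
    df = muts.df.rename(columns=inv)
    df.to_csv(path, sep="\t", index=False)


def read_arm_call_matrix(path) -> ArmCallMatrix:
    """Read a samples x arms call matrix; values coerced to {-1, 0, 1, NaN}.

    Unknown tokens become missing with a logged warning; an
    ``AneuploidyScore`` column, when present, is split out.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    score = None
    ploidy = None
    if "AneuploidyScore" in df.columns:
        score = pd.to_numeric(df.pop("AneuploidyScore"), errors="coerce")
    if "Ploidy" in df.columns:
        ploidy = pd.to_numeric(df.pop("Ploidy"), errors="coerce")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    valid = coerced.isna() | coerced.isin([-1, 0, 1])
    n_bad = int((~valid).sum().sum()) + int(
        (coerced.isna() & df.notna() & (df.astype(str) != "NA")).sum().sum()
    )
    if n_bad:
        log.warning("%s: %d out-of-alphabet arm-call cells set to missing",
                    path, n_bad)
    coerced = coerced.where(valid).astype(float)
    return ArmCallMatrix(coerced, ploidy=ploidy, aneuploidy_score=score)


def write_arm_call_matrix(calls: ArmCallMatrix, path) -> None:
    df = calls.calls.copy()
    if calls.aneuploidy_score is not None:
        df["AneuploidyScore"] = calls.aneuploidy_score
    if calls.ploidy is not None:
        df["Ploidy"] = calls.ploidy
    df.to_csv(path, sep="\t", float_format="%g", index_label="sample")


def read_gistic_tables(directory) -> GisticResult:
    """Read GISTIC-style ``focal_peaks.tsv`` / ``broad_arms.tsv`` from a directory.

    No filtering is applied at read time; q/width rules live in curation.
    """
    focal_path = os.path.join(directory, "focal_peaks.tsv")
    broad_path = os.path.join(directory, "broad_arms.tsv")
    have_focal = os.path.exists(focal_path)
    have_broad = os.path.exists(broad_path)
    if not have_focal and not have_broad:
        raise ParseError(f"{directory}: neither focal_peaks.tsv nor broad_arms.tsv found")
    if have_focal:
        focal = pd.read_csv(focal_path, sep="\t")
        if "gene" not in focal.columns:
            focal["gene"] = np.nan
        focal = focal[["peak_id", "chromosome", "start", "end", "direction",
                       "q_value", "gene"]]
    else:
        focal = pd.DataFrame(columns=["peak_id", "chromosome", "start", "end",
                                      "direction", "q_value", "gene"])
    if have_broad:
        broad = pd.read_csv(broad_path, sep="\t")[["arm", "direction", "q_value"]]
    else:
        broad = pd.DataFrame(columns=["arm", "direction", "q_value"])
    return GisticResult(focal, broad)


def write_gistic_tables(res: GisticResult, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    res.focal_peaks.to_csv(os.path.join(directory, "focal_peaks.tsv"),
                           sep="\t", index=False, float_format=FLOAT_FORMAT)
    res.broad_arms.to_csv(os.path.join(directory, "broad_arms.tsv"),
                          sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_seg(path) -> SegmentTable:
    """SEG file: sample, chromosome, start, end, log2 ratio (header required)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["sample", "chromosome", "start", "end", "log2_ratio"][: len(df.columns)]
    return SegmentTable(df)


def write_seg(segs: SegmentTable, path) -> None:
    segs.df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_clinical(path) -> pd.DataFrame:
    """Clinical table with at least (sample, time, event) columns."""
    df = pd.read_csv(path, sep="\t")
    for req in ("sample", "time", "event"):
        if req not in df.columns:
            raise ParseError(f"{path}: missing required column {req!r}")
    if (df["time"] < 0).any():
        raise ParseError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event flag must be 0/1")
    return df.set_index("sample")


def write_tsv(df: pd.DataFrame, path, index: bool = True,
              header_comment: str | None = None) -> None:
    """Write a TSV with the package-wide float format and optional provenance header."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index)
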