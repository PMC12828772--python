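"""Readers and writers for the package's tab-separated interchange formats.

All on-disk formats are plain TSV. Expression files are genes x samples with
a ``gene_id`` first column; compositions, Z-matrices and labelings are
samples x columns; clinical tables and sample maps are one row per patient
or sample. Loading enforces the container invariants and produces errors
that name the offending row/column.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CELL_TYPES,
    COMPONENTS,
    GLEASON_CATEGORIES,
    PT_CATEGORIES,
    TPM_TOTAL,
    ClinicalTable,
    CompositionMatrix,
    DataValidationError,
    ExpressionMatrix,
    ReferenceProfile,
    SampleMap,
    SubtypeLabeling,
)

logger = logging.getLogger(__name__)

_GLEASON_RAW = re.compile(r"^\s*(\d)\s*\+\s*(\d)\s*$")


class LoadError(ValueError):
    """Raised when an input file cannot be parsed into a valid container."""


def load_expression(path: str | Path, unit: str = "tpm") -> ExpressionMatrix:
    """Load a gene-by-sample expression TSV.

    The first column holds gene ids, the header row sample ids. Duplicate
    gene ids are collapsed by summation (the convention for multi-mapped
    annotation rows); duplicate sample ids, negative or non-numeric cells
    are rejected with an error naming the offender.
    """
    if unit not in ("tpm", "fpkm", "rpkm"):
        raise LoadError(f"unknown unit {unit!r}; expected tpm, fpkm or rpkm")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if not samples:
        raise LoadError(f"malformed header in {path}: no sample columns")
    dupes = pd.Index(samples)[pd.Index(samples).duplicated()].unique().tolist()
    if dupes:
        raise LoadError(f"duplicate sample ids in header of {path}: {dupes[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise LoadError(f"non-numeric expression for gene {bad[0]!r}, sample {col!r}")
        df[col] = numeric
    neg = df.lt(0)
    if neg.any().any():
        col = neg.any().idxmax()
        gene = df.index[neg[col].to_numpy().argmax()]
        raise LoadError(f"negative expression for gene {gene!r}, sample {col!r}")
    if df.index.has_duplicates:
        n_dupes = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene id rows by summation", n_dupes)
        df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(df, unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.rename_axis("gene_id").to_csv(path, sep="\t")


def renormalize_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every sample column to sum to one million (TPM).

    Relative gene proportions within each sample are unchanged, so the
    operation is idempotent. FPKM/RPKM inputs are converted to TPM-scale
    relative abundances this way before deconvolution. An all-zero sample
    column cannot be renormalized and is an error.
    """
    sums = expr.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise DataValidationError(f"cannot renormalize all-zero sample column(s): {zero[:5]}")
    scaled = expr.data * (TPM_TOTAL / sums)
    return ExpressionMatrix(scaled, unit="tpm")


def map_gleason(raw: str) -> str:
    """Map a raw Gleason "a+b" pattern string to the three-level category.

    Total score >= 8 (which covers 4+4 and 4+5 or above) is high-grade,
    4+3 is intermediate-grade, everything else is low-grade.
    """
    m = _GLEASON_RAW.match(str(raw))
    if not m:
        raise LoadError(f"cannot parse Gleason pattern {raw!r}; expected 'a+b'")
    a, b = int(m.group(1)), int(m.group(2))
    if a + b >= 8:
        return "high"
    if (a, b) == (4, 3):
        return "intermediate"
    return "low"


def load_clinical(path: str | Path) -> ClinicalTable:
    """Load a per-patient clinical TSV.

    Requires columns ``patient_id``, ``followup_months``, ``bcr_event``,
    ``pt_category`` and either ``gleason_category`` or raw ``gleason_raw``
    "a+b" strings (mapped to the three-level category). Rows with missing
    survival fields are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = ["patient_id", "followup_months", "bcr_event", "pt_category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"clinical table missing columns: {missing}")
    if "gleason_category" not in df.columns:
        if "gleason_raw" not in df.columns:
            raise LoadError("clinical table needs gleason_category or gleason_raw")
        df["gleason_category"] = df["gleason_raw"].map(map_gleason)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise LoadError(f"duplicate patient ids: {dupes[:5]}")
    n_before = len(df)
    df = df.dropna(subset=["followup_months", "bcr_event"])
    if len(df) < n_before:
        logger.info("dropped %d patients with missing survival fields", n_before - len(df))
    bad_gleason = set(df["gleason_category"].dropna()) - set(GLEASON_CATEGORIES)
    if bad_gleason:
        raise LoadError(
            f"unknown gleason_category values {sorted(bad_gleason)}; "
            f"allowed: {list(GLEASON_CATEGORIES)}"
        )
    bad_pt = set(df["pt_category"].dropna()) - set(PT_CATEGORIES)
    if bad_pt:
        raise LoadError(
            f"unknown pt_category values {sorted(bad_pt)}; allowed: {list(PT_CATEGORIES)}"
        )
    if (df["followup_months"] <= 0).any():
        bad = df.loc[df["followup_months"] <= 0, "patient_id"].tolist()
        raise LoadError(f"non-positive follow-up time for patients {bad[:5]}")
    df["bcr_event"] = df["bcr_event"].astype(int)
    return ClinicalTable(df.set_index("patient_id"))


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.rename_axis("patient_id").to_csv(path, sep="\t")


def load_sample_map(path: str | Path) -> SampleMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "patient_id", "focus_id") if c not in df.columns]
    if missing:
        raise LoadError(f"sample map missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise LoadError(f"duplicate sample ids in sample map: {dupes[:5]}")
    return SampleMap(df.set_index("sample_id"))


def write_sample_map(sample_map: SampleMap, path: str | Path) -> None:
    sample_map.data.rename_axis("sample_id").to_csv(path, sep="\t")


def load_reference(path: str | Path) -> ReferenceProfile:
    """Load a reference profile TSV: gene_id, one column per cell type,
    and a ``variability`` column carrying the per-gene weighting term."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in list(CELL_TYPES) + ["variability"] if c not in df.columns]
    if missing:
        raise LoadError(f"reference profile missing columns: {missing}")
    return ReferenceProfile(df[list(CELL_TYPES)], df["variability"])


def write_reference(ref: ReferenceProfile, path: str | Path) -> None:
    out = ref.means.copy()
    out["variability"] = ref.variability
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def load_composition(path: str | Path) -> CompositionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    residual = None
    if "fit_residual" in df.columns:
        residual = df.pop("fit_residual")
    return CompositionMatrix(df[list(COMPONENTS)], residual)


def write_composition(comp: CompositionMatrix, path: str | Path) -> None:
    out = comp.proportions.copy()
    out["fit_residual"] = comp.fit_residual
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def load_labels(path: str | Path) -> SubtypeLabeling:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" in df.columns:
        idx = "sample_id"
    elif "patient_id" in df.columns:
        idx = "patient_id"
    else:
        raise LoadError("labels file needs a sample_id or patient_id column")
    if "subtype" not in df.columns:
        raise LoadError("labels file needs a subtype column")
    return SubtypeLabeling(df.set_index(idx)["subtype"])


def write_labels(labeling: SubtypeLabeling, path: str | Path, id_name: str = "sample_id") -> None:
    labeling.labels.rename("subtype").rename_axis(id_name).to_csv(path, sep="\t")
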