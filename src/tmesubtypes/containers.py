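"""Core in-memory containers shared by all pipeline stages.

Conventions used throughout the package:

* expression matrices are genes x samples (genes are rows);
* compositions and Z-matrices are samples x components (samples are rows);
* the seven deconvolved cell types are listed in :data:`CELL_TYPES` and the
  remainder fraction is named ``uncharacterized``, giving the eight
  components in :data:`COMPONENTS`;
* the three composition subtypes are named TCE (T-cells enriched), EPCE
  (epithelial-cells enriched) and TASCE (tumor-associated-stromal-cells
  enriched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES: tuple[str, ...] = (
    "Bcells",
    "CD4_Tcells",
    "CD8_Tcells",
    "NKcells",
    "Macrophages",
    "Endothelial",
    "CAFs",
)
UNCHARACTERIZED = "uncharacterized"
COMPONENTS: tuple[str, ...] = CELL_TYPES + (UNCHARACTERIZED,)

SUBTYPES: tuple[str, ...] = ("TCE", "EPCE", "TASCE")

GLEASON_CATEGORIES: tuple[str, ...] = ("low", "intermediate", "high")
PT_CATEGORIES: tuple[str, ...] = ("T2", "T3a", "T3b")

TPM_TOTAL = 1_000_000.0


class DataValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression levels in within-sample relative units.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns; values must be finite and non-negative.
    unit
        One of ``tpm``, ``fpkm`` or ``rpkm``. FPKM/RPKM matrices must be
        passed through :func:`tmesubtypes.io.renormalize_tpm` before
        deconvolution.
    """

    data: pd.DataFrame
    unit: str = "tpm"

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "fpkm", "rpkm"):
            raise DataValidationError(f"unknown expression unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataValidationError(
                f"non-finite expression at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative expression at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ClinicalTable:
    """Per-patient follow-up for the biochemical-recurrence (BCR) endpoint.

    ``data`` is indexed by patient id with columns ``followup_months``
    (time to BCR or censoring, strictly positive), ``bcr_event`` (0/1),
    ``gleason_category`` (low / intermediate / high) and ``pt_category``
    (T2 / T3a / T3b); an optional ``age`` column is carried through.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate patient ids: {dupes[:5]}")
        required = ("followup_months", "bcr_event", "gleason_category", "pt_category")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataValidationError(f"clinical table missing columns: {missing}")
        if (df["followup_months"] <= 0).any():
            bad = df.index[df["followup_months"] <= 0].tolist()
            raise DataValidationError(f"non-positive follow-up time for patients {bad[:5]}")
        if not df["bcr_event"].isin([0, 1]).all():
            raise DataValidationError("bcr_event must be 0 or 1")
        bad_gleason = set(df["gleason_category"]) - set(GLEASON_CATEGORIES)
        if bad_gleason:
            raise DataValidationError(
                f"unknown gleason_category values {sorted(bad_gleason)}; "
                f"allowed: {list(GLEASON_CATEGORIES)}"
            )
        bad_pt = set(df["pt_category"]) - set(PT_CATEGORIES)
        if bad_pt:
            raise DataValidationError(
                f"unknown pt_category values {sorted(bad_pt)}; allowed: {list(PT_CATEGORIES)}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_patients(self) -> int:
        return len(self.data)


@dataclass
class SampleMap:
    """Sample -> (patient, focus) assignment for multisample cohorts.

    ``data`` is indexed by sample id with columns ``patient_id`` and
    ``focus_id``; focus ids are meaningful only within their patient.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dupes[:5]}")
        missing = [c for c in ("patient_id", "focus_id") if c not in df.columns]
        if missing:
            raise DataValidationError(f"sample map missing columns: {missing}")
        if df[["patient_id", "focus_id"]].isna().any().any():
            raise DataValidationError("sample map contains missing patient/focus ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def patient_of(self, sample_id: str) -> str:
        return self.data.at[sample_id, "patient_id"]


@dataclass
class ReferenceProfile:
    """Signature-gene expression means and variability per reference cell type.

    ``means`` is genes x cell types (TPM-like scale); ``variability`` is a
    per-gene non-negative series used as the inverse-variance weighting in
    the constrained least-squares fit. The identifiability invariant — every
    cell type owns at least one gene on which its mean strictly dominates all
    other types — is checked at construction.
    """

    means: pd.DataFrame
    variability: pd.Series

    def __post_init__(self) -> None:
        if list(self.means.columns) != list(CELL_TYPES):
            raise DataValidationError(
                f"reference cell types must be {list(CELL_TYPES)}, got {list(self.means.columns)}"
            )
        if (self.means.to_numpy() < 0).any():
            raise DataValidationError("reference means must be non-negative")
        if (self.variability.to_numpy() < 0).any():
            raise DataValidationError("reference variability must be non-negative")
        if not self.means.index.equals(self.variability.index):
            raise DataValidationError("means and variability gene ids differ")
        vals = self.means.to_numpy()
        top = vals.argmax(axis=1)
        strict = vals.max(axis=1) > np.partition(vals, -2, axis=1)[:, -2]
        owners = set(np.asarray(top)[strict])
        if owners != set(range(len(CELL_TYPES))):
            orphans = [CELL_TYPES[i] for i in range(len(CELL_TYPES)) if i not in owners]
            raise DataValidationError(
                f"reference not identifiable: no dominating signature gene for {orphans}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def cell_type_names(self) -> list[str]:
        return list(self.means.columns)


@dataclass
class CompositionMatrix:
    """Per-sample proportions of the 7 cell types plus the uncharacterized rest.

    ``proportions`` is samples x 8 components; each row lies on the simplex
    (entries in [0, 1], summing to 1 within 1e-9). ``fit_residual`` is the
    weighted least-squares objective at the solution, NaN for compositions
    that were not produced by deconvolution (e.g. simulated ground truth).
    """

    proportions: pd.DataFrame
    fit_residual: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.proportions.columns) != list(COMPONENTS):
            raise DataValidationError(
                f"composition components must be {list(COMPONENTS)}, "
                f"got {list(self.proportions.columns)}"
            )
        vals = self.proportions.to_numpy()
        if ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise DataValidationError("proportions outside [0, 1]")
        sums = vals.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            worst = self.proportions.index[np.abs(sums - 1.0).argmax()]
            raise DataValidationError(f"composition row does not sum to 1 for sample {worst!r}")
        if self.fit_residual is None:
            self.fit_residual = pd.Series(np.nan, index=self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)


@dataclass
class ZMatrix:
    """Component-wise standardized compositions (per component across samples).

    Constant raw columns are mapped to all-zero and recorded in
    ``constant_components``.
    """

    z_values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    constant_components: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z_values.index)

    @property
    def component_names(self) -> list[str]:
        return list(self.z_values.columns)


@dataclass
class SubtypeLabeling:
    """Assignment of samples (or patients) to the three composition subtypes.

    ``labels`` maps id -> subtype name; ``cluster_to_name`` records the
    bijection between raw cluster indices and subtype names; ``enrichment``
    is the per-cluster mean Z per component used for the naming.
    """

    labels: pd.Series
    cluster_to_name: dict[int, str] | None = None
    enrichment: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = set(self.labels.unique()) - set(SUBTYPES)
        if unknown:
            raise DataValidationError(
                f"unknown subtype labels {sorted(unknown)}; allowed: {list(SUBTYPES)}"
            )
        if self.cluster_to_name is not None:
            names = list(self.cluster_to_name.values())
            if len(set(names)) != len(names):
                raise DataValidationError("cluster_to_name must be a bijection")

    @property
    def ids(self) -> list[str]:
        return list(self.labels.index)
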