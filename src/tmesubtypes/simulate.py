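"""Synthetic bulk-RNA-seq cohorts with known cell-type composition ground truth.

The generator emulates the data-generating structure of a multifocal
prostate-cancer cohort study:

* bulk expression is a convex mixture of 7 reference cell-type profiles plus
  an epithelial profile (the component deconvolution must recover as
  "uncharacterized"), with multiplicative log-normal gene noise;
* each patient carries one of three planted composition subtypes (TCE, EPCE,
  TASCE) drawn from a prior, and a patient-level composition drawn from a
  subtype-specific Dirichlet;
* focus- and sample-level compositions derive from the patient composition by
  additive Gaussian perturbation in centered-log-ratio space followed by
  softmax back onto the simplex, giving nested patient/focus/sample variance;
* time to biochemical recurrence is exponential with subtype hazard ratios
  (TCE is the reference), independently censored at Uniform(0, max follow-up);
* Gleason-grade and pT-stage categories are drawn from subtype-conditional
  multinomials that make TASCE high-grade-enriched and TCE low-grade-enriched.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from the config, so a config fully determines the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .containers import (
    CELL_TYPES,
    COMPONENTS,
    GLEASON_CATEGORIES,
    PT_CATEGORIES,
    SUBTYPES,
    TPM_TOTAL,
    ClinicalTable,
    ExpressionMatrix,
    ReferenceProfile,
    SampleMap,
)

logger = logging.getLogger(__name__)

#: Default event fraction: 52 BCR events among 405 patients with follow-up.
DEFAULT_EVENT_FRACTION = 52 / 405

#: Univariable hazard ratios of the non-reference subtypes vs TCE.
DEFAULT_HR_EPCE = 5.3
DEFAULT_HR_TASCE = 10.9

# Dirichlet concentration per subtype over the 8 mixing components
# (7 cell types + epithelial, in COMPONENTS order). Totals are equal (200)
# so within-subtype dispersion is comparable; the means plant the subtype
# signatures: TCE's T-cell components are highest, EPCE's epithelial is
# highest, TASCE's macrophage/endothelial/CAF block is highest.
DEFAULT_DIRICHLET_ALPHA: dict[str, tuple[float, ...]] = {
    "TCE": (6.0, 22.0, 22.0, 5.0, 8.0, 10.0, 10.0, 117.0),
    "EPCE": (2.4, 3.6, 3.6, 1.6, 4.8, 6.0, 8.0, 170.0),
    "TASCE": (4.0, 6.0, 6.0, 3.0, 20.0, 22.0, 32.0, 107.0),
}

# Subtype-conditional category probabilities over (low, intermediate, high)
# and (T2, T3a, T3b): TASCE is enriched for high grade / advanced stage,
# TCE for low grade / organ-confined disease.
DEFAULT_GLEASON_PROBS: dict[str, tuple[float, ...]] = {
    "TCE": (0.70, 0.20, 0.10),
    "EPCE": (0.50, 0.30, 0.20),
    "TASCE": (0.25, 0.30, 0.45),
}
DEFAULT_PT_PROBS: dict[str, tuple[float, ...]] = {
    "TCE": (0.70, 0.22, 0.08),
    "EPCE": (0.55, 0.30, 0.15),
    "TASCE": (0.35, 0.35, 0.30),
}


def event_fraction_one_group(rate: float, censoring_max: float) -> float:
    """P(event observed) for Exponential(rate) failure and U(0, cmax) censoring."""
    x = rate * censoring_max
    return 1.0 - (1.0 - np.exp(-x)) / x


def solve_baseline_hazard(
    target_event_fraction: float,
    hr_epce: float,
    hr_tasce: float,
    subtype_prior: tuple[float, float, float],
    censoring_max_months: float,
) -> float:
    """Baseline (TCE) hazard rate giving the target cohort event fraction.

    Solves the analytic mixture event probability of the
    exponential / uniform-censoring model for the baseline rate.
    """
    hrs = np.array([1.0, hr_epce, hr_tasce])
    prior = np.asarray(subtype_prior)

    def overall(rate: float) -> float:
        probs = [event_fraction_one_group(rate * h, censoring_max_months) for h in hrs]
        return float(prior @ probs) - target_event_fraction

    return brentq(overall, 1e-8, 10.0, xtol=1e-14)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Perturbation scales (``sd_patient``, ``sd_focus``, ``sd_sample``) act per
    component in centered-log-ratio space; ``noise_sd`` is the standard
    deviation of the per-gene multiplicative log-normal expression noise.
    ``baseline_hazard`` defaults to the rate (per month) that yields an
    expected event fraction of 52/405 under the default hazard ratios and
    120-month uniform censoring.
    """

    n_patients: int = 300
    foci_per_patient: tuple[int, int] = (1, 1)
    samples_per_focus: tuple[int, int] = (1, 1)
    n_signature_genes_per_type: int = 30
    n_background_genes: int = 90
    subtype_prior: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    dirichlet_alpha: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DIRICHLET_ALPHA)
    )
    sd_patient: float = 0.05
    sd_focus: float = 0.15
    sd_sample: float = 0.08
    noise_sd: float = 0.10
    baseline_hazard: float | None = None
    hr_epce: float = DEFAULT_HR_EPCE
    hr_tasce: float = DEFAULT_HR_TASCE
    censoring_max_months: float = 120.0
    gleason_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GLEASON_PROBS)
    )
    pt_probs: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_PT_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard is None:
            self.baseline_hazard = solve_baseline_hazard(
                DEFAULT_EVENT_FRACTION,
                self.hr_epce,
                self.hr_tasce,
                self.subtype_prior,
                self.censoring_max_months,
            )
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("foci_per_patient", "samples_per_focus"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} range must satisfy 1 <= lo <= hi, got ({lo}, {hi})")
        if self.n_signature_genes_per_type < 1 or self.n_background_genes < 1:
            raise ValueError("gene counts must be >= 1")
        prior = np.asarray(self.subtype_prior, dtype=float)
        if prior.shape != (3,) or (prior < 0).any() or abs(prior.sum() - 1) > 1e-9:
            raise ValueError("subtype_prior must be 3 non-negative values summing to 1")
        for subtype in SUBTYPES:
            alpha = np.asarray(self.dirichlet_alpha[subtype], dtype=float)
            if alpha.shape != (len(COMPONENTS),) or (alpha <= 0).any():
                raise ValueError(f"dirichlet_alpha[{subtype}] must be {len(COMPONENTS)} positives")
        for name in ("sd_patient", "sd_focus", "sd_sample", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("baseline_hazard", "hr_epce", "hr_tasce", "censoring_max_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for probs in (self.gleason_probs, self.pt_probs):
            for subtype in SUBTYPES:
                p = np.asarray(probs[subtype], dtype=float)
                if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                    raise ValueError(f"category probabilities for {subtype} must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("foci_per_patient", "samples_per_focus", "subtype_prior"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("dirichlet_alpha", "gleason_probs", "pt_probs"):
            if key in raw:
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class SyntheticTruth:
    """Ground truth echoed by the generator for recovery tests.

    ``sample_proportions`` holds the true 8-component mixing vector per
    sample (the epithelial component under the ``uncharacterized`` name);
    ``patient_log_hazard`` is the true log hazard relative to baseline.
    """

    sample_proportions: pd.DataFrame
    sample_subtype: pd.Series
    patient_subtype: pd.Series
    patient_log_hazard: pd.Series
    config: SimulationConfig


def generate_reference(
    n_genes_per_type: int = 30, n_background_genes: int = 90, seed: int = 0
) -> ReferenceProfile:
    """Construct a block-structured synthetic reference profile.

    Each cell type owns ``n_genes_per_type`` signature genes on which its
    mean expression is high (the other types leak only a low level);
    background genes are expressed by none of the 7 reference types — in the
    paired cohort generator they are epithelial-specific, which keeps the
    epithelial profile orthogonal to the reference block. Columns are scaled
    to TPM (sum one million) so convex mixtures of profiles are TPM too.
    Per-gene variability weights are log-normal.
    """
    if n_genes_per_type < 1 or n_background_genes < 1:
        raise ValueError("gene counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_types = len(CELL_TYPES)
    n_sig = n_genes_per_type * n_types
    genes = [
        f"SIG_{ct}_{i:03d}" for ct in CELL_TYPES for i in range(n_genes_per_type)
    ] + [f"BG_{i:03d}" for i in range(n_background_genes)]
    means = np.zeros((n_sig + n_background_genes, n_types))
    for t in range(n_types):
        rows = slice(t * n_genes_per_type, (t + 1) * n_genes_per_type)
        leak = rng.uniform(0.0, 20.0, size=(n_genes_per_type, n_types))
        leak[:, t] = rng.uniform(200.0, 1000.0, size=n_genes_per_type)
        means[rows] = leak
    means *= TPM_TOTAL / means.sum(axis=0, keepdims=True)
    variability = rng.lognormal(mean=0.0, sigma=0.5, size=n_sig + n_background_genes)
    return ReferenceProfile(
        pd.DataFrame(means, index=genes, columns=list(CELL_TYPES)),
        pd.Series(variability, index=genes, name="variability"),
    )


def epithelial_profile(ref: ReferenceProfile, rng: np.random.Generator) -> pd.Series:
    """Epithelial expression column over the reference's genes, TPM scale.

    Expressed only on the background genes, so it is orthogonal to every
    reference cell-type column and must be absorbed by the uncharacterized
    remainder during deconvolution.
    """
    genes = ref.means.index
    background = genes.str.startswith("BG_")
    if not background.any():
        raise ValueError("reference has no background genes for the epithelial profile")
    profile = np.zeros(len(genes))
    profile[background] = rng.uniform(200.0, 1000.0, size=int(background.sum()))
    profile *= TPM_TOTAL / profile.sum()
    return pd.Series(profile, index=genes, name="epithelial")


def _clr(p: np.ndarray) -> np.ndarray:
    logp = np.log(p)
    return logp - logp.mean(axis=-1, keepdims=True)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def perturb_simplex(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Jitter a simplex vector by N(0, sd^2) in centered-log-ratio space."""
    if sd == 0:
        return p.copy()
    return _softmax(_clr(p) + rng.normal(0.0, sd, size=p.shape))


def simulate_cohort(
    cfg: SimulationConfig, ref: ReferenceProfile
) -> tuple[ExpressionMatrix, SampleMap, ClinicalTable, SyntheticTruth]:
    """Draw a full synthetic cohort under ``cfg`` using reference ``ref``.

    Returns the TPM bulk expression matrix, the sample -> patient/focus map,
    the per-patient clinical table and the ground truth. Deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    epi = epithelial_profile(ref, rng)
    mix_basis = np.column_stack([ref.means.to_numpy(), epi.to_numpy()])  # genes x 8

    alpha = {s: np.asarray(cfg.dirichlet_alpha[s], dtype=float) for s in SUBTYPES}
    hr = {"TCE": 1.0, "EPCE": cfg.hr_epce, "TASCE": cfg.hr_tasce}

    sample_rows: list[dict] = []
    sample_props: list[np.ndarray] = []
    clin_rows: list[dict] = []
    pat_subtypes: dict[str, str] = {}
    pat_loghaz: dict[str, float] = {}

    for p in range(cfg.n_patients):
        pid = f"P{p + 1:04d}"
        subtype = SUBTYPES[rng.choice(3, p=np.asarray(cfg.subtype_prior))]
        base = rng.dirichlet(alpha[subtype])
        p_pat = perturb_simplex(base, cfg.sd_patient, rng)
        pat_subtypes[pid] = subtype
        pat_loghaz[pid] = float(np.log(hr[subtype]))

        n_foci = int(rng.integers(cfg.foci_per_patient[0], cfg.foci_per_patient[1] + 1))
        for f in range(n_foci):
            fid = f"F{f + 1}"
            p_focus = perturb_simplex(p_pat, cfg.sd_focus, rng)
            n_samples = int(rng.integers(cfg.samples_per_focus[0], cfg.samples_per_focus[1] + 1))
            for s in range(n_samples):
                sid = f"{pid}_{fid}_S{s + 1}"
                p_sample = perturb_simplex(p_focus, cfg.sd_sample, rng)
                sample_rows.append(
                    {"sample_id": sid, "patient_id": pid, "focus_id": fid, "subtype": subtype}
                )
                sample_props.append(p_sample)

        rate = cfg.baseline_hazard * hr[subtype]
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.uniform(0.0, cfg.censoring_max_months)
        event = int(t_event <= t_censor)
        followup = max(min(t_event, t_censor), 1e-3)
        gleason = GLEASON_CATEGORIES[rng.choice(3, p=np.asarray(cfg.gleason_probs[subtype]))]
        pt = PT_CATEGORIES[rng.choice(3, p=np.asarray(cfg.pt_probs[subtype]))]
        clin_rows.append(
            {
                "patient_id": pid,
                "followup_months": followup,
                "bcr_event": event,
                "gleason_category": gleason,
                "pt_category": pt,
            }
        )

    props = np.vstack(sample_props)  # n_samples x 8
    expr = mix_basis @ props.T  # genes x n_samples
    if cfg.noise_sd > 0:
        expr = expr * rng.lognormal(mean=0.0, sigma=cfg.noise_sd, size=expr.shape)
    expr *= TPM_TOTAL / expr.sum(axis=0, keepdims=True)

    sample_ids = [r["sample_id"] for r in sample_rows]
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=ref.means.index, columns=sample_ids), unit="tpm"
    )
    sample_map = SampleMap(
        pd.DataFrame(sample_rows).set_index("sample_id")[["patient_id", "focus_id"]]
    )
    clinical = ClinicalTable(pd.DataFrame(clin_rows).set_index("patient_id"))
    truth = SyntheticTruth(
        sample_proportions=pd.DataFrame(props, index=sample_ids, columns=list(COMPONENTS)),
        sample_subtype=pd.Series(
            [r["subtype"] for r in sample_rows], index=sample_ids, name="subtype"
        ),
        patient_subtype=pd.Series(pat_subtypes, name="subtype"),
        patient_log_hazard=pd.Series(pat_loghaz, name="log_hazard"),
        config=cfg,
    )
    n_events = sum(r["bcr_event"] for r in clin_rows)
    logger.info(
        "simulated %d patients / %d samples, %d BCR events (%.1f%%)",
        cfg.n_patients,
        len(sample_ids),
        n_events,
        100 * n_events / cfg.n_patients,
    )
    return expression, sample_map, clinical, truth


def simulate_multifocal_defaults(seed: int = 0) -> SimulationConfig:
    """Default config for a multifocal (Oslo-like) cohort.

    23 patients with 2-3 spatially separated foci each and 1-2 samples per
    focus (~86 samples in expectation). Focus-level composition variance
    dominates completely: all subtypes share one pooled, highly concentrated
    Dirichlet and ``sd_patient`` is zero, so patient identity carries no
    compositional signal, while ``sd_focus`` exceeds ``sd_sample``. Under
    this regime intrafocal sample pairs are far more similar than interfocal
    pairs, and interfocal pairs are statistically indistinguishable from
    interpatient pairs — the multifocal heterogeneity ordering
    (intrafocal > interfocal ~ interpatient). Any appreciable patient-level
    variance is detectable by the all-pairs rank-sum comparison through the
    thousands of correlated interpatient pairs, which is why the patient
    level is degenerate in this config (see the methods note).
    """
    pooled = np.mean([np.asarray(a) for a in DEFAULT_DIRICHLET_ALPHA.values()], axis=0)
    shared = {s: tuple(100.0 * pooled) for s in DEFAULT_DIRICHLET_ALPHA}
    return SimulationConfig(
        n_patients=23,
        foci_per_patient=(2, 3),
        samples_per_focus=(1, 2),
        dirichlet_alpha=shared,
        sd_patient=0.0,
        sd_focus=0.50,
        sd_sample=0.40,
        seed=seed,
    )


def analytic_event_fraction(cfg: SimulationConfig) -> float:
    """Expected fraction of patients with an observed BCR event under ``cfg``."""
    hrs = np.array([1.0, cfg.hr_epce, cfg.hr_tasce])
    prior = np.asarray(cfg.subtype_prior)
    probs = [
        event_fraction_one_group(cfg.baseline_hazard * h, cfg.censoring_max_months) for h in hrs
    ]
    return float(prior @ probs)


def truth_composition(truth: SyntheticTruth):
    """Ground-truth proportions as a CompositionMatrix (for generator-as-oracle tests)."""
    from .containers import CompositionMatrix

    props = truth.sample_proportions.copy()
    # guard against accumulated float error in the softmax mapping
    props = props.div(props.sum(axis=1), axis=0)
    return CompositionMatrix(props)
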