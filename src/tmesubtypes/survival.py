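"""Time-to-biochemical-recurrence analysis of composition subtypes.

Kaplan-Meier curves with k-group log-rank tests, Cox proportional-hazards
models on categorical covariates (subtype, Gleason grade, pT stage, each
with a declared reference level), Harrell's concordance index, and the
Grambsch-Therneau scaled-Schoenfeld check of the proportional-hazards
assumption. Model fitting is delegated to ``lifelines`` (Newton-Raphson on
the Efron-tie partial likelihood); this module owns the categorical
encoding, reference levels, complete-case handling and result containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy.stats import chi2

from .containers import ClinicalTable, SubtypeLabeling

logger = logging.getLogger(__name__)

#: Reference level per covariate (the baseline row of the hazard-ratio table).
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "subtype": "TCE",
    "gleason": "low",
    "pt": "T2",
}

_COVARIATE_COLUMNS = {"gleason": "gleason_category", "pt": "pt_category"}

#: Kaplan-Meier points with fewer subjects at risk are flagged for plot truncation.
KM_TRUNCATION_AT_RISK = 5


class SurvivalError(ValueError):
    """Raised for unusable survival inputs or failed fits."""


@dataclass
class KmCurve:
    """Product-limit estimate for one group, with plot-truncation flags."""

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    truncated: np.ndarray  # True where at-risk < KM_TRUNCATION_AT_RISK


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SurvivalFit:
    """A fitted Cox model: per-level hazard ratios plus fit diagnostics."""

    terms: pd.DataFrame  # index: encoded term; columns: coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    concordance: float
    n_subjects: int
    n_events: int
    covariates: list[str]
    reference_levels: dict[str, str]
    fitter: CoxPHFitter = field(repr=False)
    design: pd.DataFrame = field(repr=False)
    #: encoded terms whose contrast has no finite MLE (a level with zero
    #: events gives a monotone partial likelihood; the reported coefficient
    #: and CI for these terms are boundary artifacts)
    non_identifiable: list[str] = field(default_factory=list)


def _assemble(
    clinical: ClinicalTable,
    covariates: list[str],
    subtypes: SubtypeLabeling | pd.Series | None,
    reference_levels: dict[str, str],
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Complete-case design matrix with reference-dropped dummy coding."""
    df = clinical.data[["followup_months", "bcr_event"]].copy()
    for cov in covariates:
        if cov == "subtype":
            if subtypes is None:
                raise SurvivalError("covariate 'subtype' requested but no labels supplied")
            series = subtypes.labels if isinstance(subtypes, SubtypeLabeling) else subtypes
            df["subtype"] = series.reindex(df.index)
        elif cov in _COVARIATE_COLUMNS:
            df[cov] = clinical.data[_COVARIATE_COLUMNS[cov]]
        else:
            raise SurvivalError(f"unknown covariate {cov!r}; expected subtype, gleason or pt")
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("complete-case analysis: dropped %d subjects with missing covariates",
                    n_before - len(df))
    # levels with zero events have no finite MLE for their contrast
    non_identifiable: list[str] = []
    for cov in covariates:
        events_by_level = df.groupby(cov, observed=True)["bcr_event"].sum()
        zero_levels = events_by_level.index[events_by_level == 0].tolist()
        for level in zero_levels:
            ref = reference_levels[cov]
            if level == ref:  # all contrasts of this covariate diverge
                non_identifiable.extend(
                    f"{cov}_{lv}" for lv in sorted(set(df[cov].unique()) - {ref})
                )
            else:
                non_identifiable.append(f"{cov}_{level}")
            logger.warning(
                "covariate %r level %r has zero events; its hazard-ratio contrast "
                "is not identifiable (coefficient diverges)", cov, level
            )
    encoded_cols: list[str] = []
    for cov in covariates:
        ref = reference_levels[cov]
        levels = [ref] + sorted(set(df[cov].unique()) - {ref})
        if ref not in set(df[cov]):
            raise SurvivalError(f"reference level {ref!r} absent from covariate {cov!r}")
        cat = pd.Categorical(df[cov], categories=levels)
        dummies = pd.get_dummies(cat, prefix=cov, drop_first=True, dtype=float)
        dummies.index = df.index
        df = pd.concat([df.drop(columns=cov), dummies], axis=1)
        encoded_cols.extend(dummies.columns)
    return df, encoded_cols, non_identifiable


def km_estimate(
    clinical: ClinicalTable, groups: SubtypeLabeling | pd.Series
) -> tuple[dict[str, KmCurve], LogrankResult]:
    """Kaplan-Meier curve per group and the k-group log-rank test.

    The truncation flag (at-risk < 5) marks points that a rendering layer
    should suppress; the log-rank test always uses the full data.
    """
    series = groups.labels if isinstance(groups, SubtypeLabeling) else groups
    series = series.reindex(clinical.data.index).dropna()
    clin = clinical.data.loc[series.index]
    curves: dict[str, KmCurve] = {}
    for name, members in series.groupby(series):
        sub = clin.loc[members.index]
        if len(sub) == 0:
            raise SurvivalError(f"group {name!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["followup_months"], sub["bcr_event"])
        table = kmf.event_table
        table = table[table["removed"] > 0]  # drop the synthetic t=0 baseline row
        times = table.index.to_numpy(dtype=float)
        at_risk = table["at_risk"].to_numpy(dtype=float)
        events = table["observed"].to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
        curves[str(name)] = KmCurve(
            group=str(name),
            times=times,
            at_risk=at_risk,
            events=events,
            survival=surv,
            truncated=at_risk < KM_TRUNCATION_AT_RISK,
        )
    lr = multivariate_logrank_test(
        clin["followup_months"], series, clin["bcr_event"]
    )
    n_groups = series.nunique()
    return curves, LogrankResult(float(lr.test_statistic), n_groups - 1, float(lr.p_value))


def cox_fit(
    clinical: ClinicalTable,
    covariates: list[str],
    subtypes: SubtypeLabeling | pd.Series | None = None,
    reference_levels: dict[str, str] | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit on categorical covariates.

    Efron tie handling, Wald 95% CIs and p-values, Harrell's concordance
    from the fitted linear predictor. Diverging coefficients (|coef| > 20)
    indicate complete separation and raise with guidance.
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    df, encoded, non_identifiable = _assemble(clinical, covariates, subtypes, refs)
    n_events = int(df["bcr_event"].sum())
    if n_events < 1:
        raise SurvivalError("no events in the data; cannot fit a Cox model")
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="followup_months", event_col="bcr_event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        if non_identifiable:
            raise SurvivalError(
                f"Cox model failed to converge and term(s) {non_identifiable} have a "
                "zero-event level (complete separation): merge sparse categories or "
                "drop the covariate"
            ) from exc
        raise SurvivalError(f"Cox model failed to converge: {exc}") from exc
    summary = fitter.summary
    diverging = summary.index[summary["coef"].abs() > 20].difference(non_identifiable)
    if len(diverging):
        raise SurvivalError(
            f"diverging coefficient(s) {diverging.tolist()}: likely complete separation; "
            "merge sparse categories or drop the covariate"
        )
    terms = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "se": summary["se(coef)"],
            "p": summary["p"],
        }
    ).loc[encoded]
    return SurvivalFit(
        terms=terms,
        log_likelihood=float(fitter.log_likelihood_),
        concordance=float(fitter.concordance_index_),
        n_subjects=len(df),
        n_events=n_events,
        covariates=list(covariates),
        reference_levels={c: refs[c] for c in covariates},
        fitter=fitter,
        design=df,
        non_identifiable=non_identifiable,
    )


def concordance_index(
    risk_scores: pd.Series | np.ndarray, clinical: ClinicalTable
) -> float:
    """Harrell's C for risk scores (higher score = higher hazard).

    Counts concordant permissible pairs under censoring; tied scores credit
    0.5. Perfect risk ordering gives 1, perfect anti-ordering 0.
    """
    if isinstance(risk_scores, pd.Series):
        scores = risk_scores.reindex(clinical.data.index).to_numpy(dtype=float)
    else:
        scores = np.asarray(risk_scores, dtype=float)
    if len(scores) != clinical.n_patients or np.isnan(scores).any():
        raise SurvivalError("risk scores must align with the clinical table")
    times = clinical.data["followup_months"].to_numpy(dtype=float)
    events = clinical.data["bcr_event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise SurvivalError("no events: no permissible pairs for the concordance index")
    # lifelines' convention: higher prediction = longer survival, so negate
    return float(_lifelines_cindex(times, -scores, events))


def ph_test(fit: SurvivalFit) -> tuple[pd.DataFrame, float]:
    """Grambsch-Therneau proportional-hazards check.

    Correlates the scaled Schoenfeld residuals with the rank of event time.
    Returns per-term chi-square p-values and a global p-value obtained by
    summing the per-term chi-squares (df = number of terms) — an
    approximation to the joint test that treats terms as independent.
    """
    if fit.n_events < 2:
        raise SurvivalError("proportional-hazards test needs at least 2 events")
    res = proportional_hazard_test(fit.fitter, fit.design, time_transform="rank")
    summary = res.summary
    if isinstance(summary.index, pd.MultiIndex):
        summary = summary.droplevel(1)
    per_term = pd.DataFrame(
        {"chi2": summary["test_statistic"], "p": summary["p"]}
    )
    global_stat = float(per_term["chi2"].sum())
    global_p = float(chi2.sf(global_stat, df=len(per_term)))
    return per_term, global_p


def model_comparison(
    clinical: ClinicalTable,
    covariate_sets: dict[str, list[str]],
    subtypes: SubtypeLabeling | pd.Series | None = None,
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Concordance index for each requested covariate combination.

    Mirrors the nested-model comparison of prognostic value: e.g. Gleason
    alone, Gleason + pT, Gleason + subtype, Gleason + pT + subtype.
    """
    rows = []
    for name, covs in covariate_sets.items():
        fit = cox_fit(clinical, covs, subtypes=subtypes, reference_levels=reference_levels)
        rows.append(
            {
                "model": name,
                "covariates": "+".join(covs),
                "concordance": fit.concordance,
                "n_subjects": fit.n_subjects,
                "n_events": fit.n_events,
            }
        )
    return pd.DataFrame(rows).set_index("model")
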