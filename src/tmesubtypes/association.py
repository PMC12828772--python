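"""Subtypes versus clinicopathological variables and CAF-marker expression.

Cross-tabulates subtype labels against Gleason-grade or pT-stage categories
(Pearson chi-square, no continuity correction, with a small-expected-count
warning flag), and compares the expression of established cancer-associated
fibroblast (CAF) markers between subtypes with pairwise Wilcoxon rank-sum
tests on log2(x + 1) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, false_discovery_control, mannwhitneyu

from .containers import ClinicalTable, ExpressionMatrix, SubtypeLabeling

logger = logging.getLogger(__name__)

#: Established CAF marker genes.
CAF_MARKERS: tuple[str, ...] = (
    "ACTA2",
    "FAP",
    "PDGFRB",
    "POSTN",
    "COL1A1",
    "FN1",
    "VIM",
    "DCN",
    "LUM",
)


@dataclass
class ContingencyResult:
    counts: pd.DataFrame  # subtypes x categories
    row_proportions: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    low_expected_counts: bool  # any expected cell count < 5


def crosstab_subtype(
    labels: SubtypeLabeling | pd.Series, categories: pd.Series
) -> ContingencyResult:
    """Subtype x category contingency table with a Pearson chi-square test.

    ``categories`` is a per-id categorical series (e.g. Gleason grade or pT
    stage) aligned to the label index; ids present in only one input are
    dropped.
    """
    series = labels.labels if isinstance(labels, SubtypeLabeling) else labels
    joined = pd.concat(
        [series.rename("subtype"), categories.rename("category")], axis=1
    ).dropna()
    if joined.empty:
        raise ValueError("no overlapping ids between labels and categories")
    counts = pd.crosstab(joined["subtype"], joined["category"])
    stat, p, dof, expected = chi2_contingency(counts.to_numpy(), correction=False)
    low = bool((expected < 5).any())
    if low:
        logger.warning("chi-square expected count < 5 in some cells; test may be unreliable")
    return ContingencyResult(
        counts=counts,
        row_proportions=counts.div(counts.sum(axis=1), axis=0),
        chi2=float(stat),
        df=int(dof),
        p_value=float(p),
        low_expected_counts=low,
    )


@dataclass
class MarkerComparison:
    """Per-marker pairwise subtype tests plus the list of absent markers."""

    table: pd.DataFrame  # marker, subtype_a, subtype_b, median_diff, p, p_bh
    missing_markers: list[str] = field(default_factory=list)


def marker_comparison(
    expr: ExpressionMatrix,
    labels: SubtypeLabeling | pd.Series,
    markers: tuple[str, ...] = CAF_MARKERS,
) -> MarkerComparison:
    """Compare marker expression between subtypes, pairwise per marker.

    Expression is log2(x + 1)-transformed; each subtype pair is tested with
    the two-sided Wilcoxon rank-sum (normal approximation with tie and
    continuity correction). ``median_diff`` is median(a) - median(b) on the
    log scale. Raw p-values are reported (matching a per-marker-stars
    presentation); a Benjamini-Hochberg column is emitted alongside.
    Markers absent from the matrix are reported, not fatal — unless none
    are present.
    """
    series = labels.labels if isinstance(labels, SubtypeLabeling) else labels
    present = [m for m in markers if m in expr.data.index]
    missing = [m for m in markers if m not in expr.data.index]
    if not present:
        raise ValueError(f"none of the markers {list(markers)} found in the expression matrix")
    if missing:
        logger.info("markers absent from expression matrix: %s", missing)

    shared = [s for s in expr.sample_ids if s in series.index]
    log_expr = np.log2(expr.data.loc[present, shared] + 1.0)
    groups = series.loc[shared]
    subtype_names = sorted(groups.unique())

    rows = []
    for marker in present:
        values = log_expr.loc[marker]
        for a, b in combinations(subtype_names, 2):
            va = values[groups == a].to_numpy()
            vb = values[groups == b].to_numpy()
            _, p = mannwhitneyu(va, vb, alternative="two-sided", method="asymptotic")
            rows.append(
                {
                    "marker": marker,
                    "subtype_a": a,
                    "subtype_b": b,
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "median_diff": float(np.median(va) - np.median(vb)),
                    "p": float(p),
                }
            )
    table = pd.DataFrame(rows)
    table["p_bh"] = false_discovery_control(table["p"], method="bh")
    return MarkerComparison(table=table, missing_markers=missing)
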