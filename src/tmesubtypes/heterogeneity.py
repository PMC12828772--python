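"""Multifocal heterogeneity of cell-type compositions.

Every unordered pair of samples in a multisample cohort is classified as

* intrafocal — same patient, same tumor focus,
* interfocal — same patient, different foci,
* interpatient — different patients,

and scored by the cosine similarity of the samples' z-scored composition
rows. Pairwise Wilcoxon rank-sum tests between the three pair classes
quantify whether composition is more conserved within a focus than across
foci or patients. Subtype concordance summarizes, per patient and per
focus, whether all samples carry one subtype label.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import SampleMap, SubtypeLabeling, ZMatrix

PAIR_CLASSES = ("intrafocal", "interfocal", "interpatient")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, clamped to [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def pair_similarities(z: ZMatrix, sample_map: SampleMap) -> pd.DataFrame:
    """All C(n, 2) sample pairs with pair class and cosine similarity.

    Returns a DataFrame with columns ``sample_a``, ``sample_b``,
    ``pair_class`` and ``cosine_similarity``.
    """
    ids = z.sample_ids
    unmapped = [s for s in ids if s not in sample_map.data.index]
    if unmapped:
        raise ValueError(f"samples missing from sample map: {unmapped[:5]}")
    X = z.z_values.to_numpy()
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [ids[i] for i in np.where(norms == 0)[0]]
        raise ValueError(f"zero-norm z rows for samples: {bad[:5]}")
    sims = np.clip((X @ X.T) / np.outer(norms, norms), -1.0, 1.0)

    patients = sample_map.data.loc[ids, "patient_id"].to_numpy()
    foci = sample_map.data.loc[ids, "focus_id"].to_numpy()
    rows = []
    for i, j in combinations(range(len(ids)), 2):
        if patients[i] != patients[j]:
            pair_class = "interpatient"
        elif foci[i] != foci[j]:
            pair_class = "interfocal"
        else:
            pair_class = "intrafocal"
        rows.append((ids[i], ids[j], pair_class, sims[i, j]))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "pair_class", "cosine_similarity"])


@dataclass
class RankSumResult:
    group_a: str
    group_b: str
    statistic: float  # Mann-Whitney U of group_a
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def compare_pair_groups(pairs: pd.DataFrame) -> dict[str, RankSumResult]:
    """Two-sided Wilcoxon rank-sum tests between the three pair classes.

    Uses the normal approximation with tie correction and continuity
    correction. P-values are reported unadjusted across the three
    comparisons. Keys are ``"intrafocal_vs_interfocal"`` etc.
    """
    groups = {
        cls: pairs.loc[pairs["pair_class"] == cls, "cosine_similarity"].to_numpy()
        for cls in PAIR_CLASSES
    }
    comparisons = [
        ("intrafocal", "interfocal"),
        ("intrafocal", "interpatient"),
        ("interfocal", "interpatient"),
    ]
    out: dict[str, RankSumResult] = {}
    for a, b in comparisons:
        if len(groups[a]) == 0 or len(groups[b]) == 0:
            empty = a if len(groups[a]) == 0 else b
            raise ValueError(f"pair class {empty!r} is empty; cannot test {a} vs {b}")
        stat, p = mannwhitneyu(
            groups[a], groups[b], alternative="two-sided", method="asymptotic"
        )
        out[f"{a}_vs_{b}"] = RankSumResult(
            a,
            b,
            float(stat),
            float(p),
            float(np.median(groups[a])),
            float(np.median(groups[b])),
            len(groups[a]),
            len(groups[b]),
        )
    return out


def subtype_concordance(
    labels: SubtypeLabeling, sample_map: SampleMap
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Per-patient and per-focus subtype uniformity.

    Returns ``(per_patient, per_focus, summary)``: patients with the number
    of distinct subtypes among their samples and a uniformity flag; foci
    with >= 2 samples likewise; and cohort counts
    ``patients_uniform / patients_total / foci_uniform / foci_multi_sample``.
    """
    df = sample_map.data.copy()
    df["subtype"] = labels.labels.reindex(df.index)
    if df["subtype"].isna().any():
        missing = df.index[df["subtype"].isna()].tolist()
        raise ValueError(f"samples without subtype labels: {missing[:5]}")

    per_patient = (
        df.groupby("patient_id")["subtype"]
        .agg(n_samples="size", n_subtypes="nunique")
        .assign(uniform=lambda t: t["n_subtypes"] == 1)
    )
    by_focus = df.groupby(["patient_id", "focus_id"])["subtype"].agg(
        n_samples="size", n_subtypes="nunique"
    )
    per_focus = by_focus[by_focus["n_samples"] >= 2].assign(
        uniform=lambda t: t["n_subtypes"] == 1
    )
    summary = {
        "patients_uniform": int(per_patient["uniform"].sum()),
        "patients_total": int(len(per_patient)),
        "foci_uniform": int(per_focus["uniform"].sum()),
        "foci_multi_sample": int(len(per_focus)),
    }
    return per_patient, per_focus, summary
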