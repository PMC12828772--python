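"""Composition subtype discovery: z-scoring, PAM consensus clustering, naming.

The subtype discovery pipeline standardizes the 8 composition components
feature-wise (each component across samples), runs resampling-based
consensus clustering with partitioning around medoids (PAM) over a range of
cluster counts, selects k from the change in area under the consensus CDF,
and names the three clusters by their enriched components:

* TCE  — T-cells enriched (highest mean z of CD4 + CD8 T cells),
* EPCE — epithelial-cells enriched (highest mean z of the uncharacterized
  fraction, which stands for malignant and benign epithelium),
* TASCE — tumor-associated-stromal-cells enriched (highest mean z of
  CAFs + endothelial cells + macrophages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import CompositionMatrix, SubtypeLabeling, UNCHARACTERIZED, ZMatrix

logger = logging.getLogger(__name__)

#: Component sets whose mean z defines each subtype's enrichment score.
NAMING_CRITERIA: dict[str, tuple[str, ...]] = {
    "TCE": ("CD4_Tcells", "CD8_Tcells"),
    "EPCE": (UNCHARACTERIZED,),
    "TASCE": ("CAFs", "Endothelial", "Macrophages"),
}


def zscore(comp: CompositionMatrix) -> ZMatrix:
    """Standardize each component across samples (mean 0, sd 1, ddof=1).

    Constant components carry no clustering information; they are mapped to
    all-zero and flagged rather than producing NaN columns.
    """
    if len(comp.sample_ids) < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    values = comp.proportions
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        logger.warning("constant composition component(s) mapped to zero: %s", constant)
    safe_sds = sds.replace(0.0, 1.0)
    z = (values - means) / safe_sds
    z[constant] = 0.0
    return ZMatrix(z, means, sds, constant)


# ---------------------------------------------------------------------------
# Partitioning around medoids (build + swap), deterministic.

def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """k-medoids clustering of a precomputed distance matrix.

    Classic build phase (greedy) followed by swap passes that apply the best
    improving (medoid, candidate) exchange until none remains. Ties are
    broken toward the lowest index, so the result is deterministic.

    Returns the medoid index of each point's cluster (length n).
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    # build: first medoid minimizes total distance, then greedy additions
    medoids = [int(dist.sum(axis=1).argmin())]
    d_near = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        best = int(gain.argmax())
        medoids.append(best)
        d_near = np.minimum(d_near, dist[:, best])

    medoids_arr = np.array(sorted(medoids))
    for _ in range(max_iter):
        dm = dist[:, medoids_arr]  # n x k
        order = dm.argsort(axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]
        d2 = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        nearest = order[:, 0]
        current_cost = d1.sum()

        best_delta = -1e-12
        best_swap: tuple[int, int] | None = None
        for j in range(k):
            # cost of each point if medoid j were removed
            removed = np.where(nearest == j, d2, d1)
            totals = np.minimum(removed[:, None], dist).sum(axis=0)  # per candidate
            totals[medoids_arr] = np.inf
            h = int(totals.argmin())
            delta = totals[h] - current_cost
            if delta < best_delta - 1e-15 or (
                best_swap is not None
                and abs(delta - best_delta) <= 1e-15
                and (medoids_arr[j], h) < best_swap
            ):
                best_delta = delta
                best_swap = (int(medoids_arr[j]), h)
        if best_swap is None:
            break
        medoids_arr = np.array(sorted(set(medoids_arr) - {best_swap[0]} | {best_swap[1]}))

    assignment = medoids_arr[dist[:, medoids_arr].argmin(axis=1)]
    return assignment


@dataclass
class ConsensusResult:
    """Resampling consensus-clustering output across the tried k values."""

    k_values: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    delta_area: dict[int, float]
    sample_ids: list[str]
    never_cosampled: int = 0
    chosen_k: int | None = None
    low_confidence: bool = False


def consensus_cluster(
    z: ZMatrix,
    k_range: tuple[int, int] = (2, 6),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampling-based consensus clustering with PAM.

    For each k: draw ``n_resamples`` subsamples of ``floor(fraction * n)``
    samples without replacement, cluster each with PAM (Euclidean distance
    on z rows), and record how often each co-sampled pair co-clusters.
    ``consensus(i, j)`` is the co-clustering count divided by the co-sampling
    count. Final labels per k come from average-linkage agglomerative
    clustering of the dissimilarity ``1 - consensus`` cut at k.

    The area under the empirical CDF of off-diagonal consensus values is
    reported per k together with its relative increase over k-1 (the
    "delta area" used for model selection).
    """
    if n_resamples < 10:
        raise ValueError("n_resamples must be >= 10")
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must be in (0, 1)")
    X = z.z_values.to_numpy()
    n = X.shape[0]
    m = int(np.floor(subsample_fraction * n))
    ks = list(range(k_range[0], k_range[1] + 1))
    if max(ks) >= m:
        raise ValueError(f"max k ({max(ks)}) must be < subsample size ({m})")

    rng = np.random.default_rng(seed)
    result = ConsensusResult(ks, {}, {}, {}, {}, list(z.z_values.index))

    full_dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    never = 0
    for k in ks:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = full_dist[np.ix_(idx, idx)]
            assignment = pam(sub, k)
            co_sample[np.ix_(idx, idx)] += 1.0
            for medoid in np.unique(assignment):
                members = idx[assignment == medoid]
                co_cluster[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        never += int(((co_sample == 0).sum() - n) // 2) if (co_sample == 0).any() else 0
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0

        dissim = 1.0 - consensus
        np.fill_diagonal(dissim, 0.0)
        Z = linkage(squareform(dissim, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1

        tri = consensus[np.triu_indices(n, k=1)]
        # area under the CDF of values supported on [0, 1]: 1 - mean
        result.consensus[k] = consensus
        result.labels[k] = labels
        result.cdf_areas[k] = float(1.0 - tri.mean())

    result.never_cosampled = never
    if never:
        logger.warning("%d sample pairs were never co-sampled; consensus set to 0", never)
    for i, k in enumerate(ks):
        if i == 0:
            result.delta_area[k] = result.cdf_areas[k]
        else:
            prev = result.cdf_areas[ks[i - 1]]
            result.delta_area[k] = max((result.cdf_areas[k] - prev) / max(prev, 1e-12), 0.0)
    return result


def select_k(res: ConsensusResult, policy: str = "delta-area", threshold: float = 0.1,
             fixed_k: int | None = None) -> int:
    """Choose the number of clusters from a consensus result.

    ``delta-area`` returns the largest k whose relative CDF-area increase
    over k-1 still exceeds ``threshold`` (the smallest k beyond which the
    profile flattens). Two degenerate situations return the smallest k with
    ``res.low_confidence`` set instead: a profile that is flat everywhere
    beyond the smallest k, and a candidate whose consensus matrix is mostly
    ambiguous (over half of the off-diagonal entries between 0.1 and 0.9 —
    structureless data keeps nominal area gains as consensus dilutes like
    1/k, but never develops the bimodal 0/1 consensus of real clusters).
    ``fixed`` returns ``fixed_k`` regardless of structure (the operative
    choice for the three-subtype model).
    """
    if len(res.k_values) < 2:
        raise ValueError("need at least 2 k values to select from")
    if policy == "fixed":
        if fixed_k is None:
            raise ValueError("policy 'fixed' requires fixed_k")
        res.chosen_k = fixed_k
        return fixed_k
    if policy != "delta-area":
        raise ValueError(f"unknown policy {policy!r}")
    ks = res.k_values
    supported = [k for k in ks[1:] if res.delta_area[k] >= threshold]
    if not supported:
        res.low_confidence = True
        res.chosen_k = ks[0]
        logger.warning(
            "flat consensus-CDF area profile: no k beyond %d is supported; "
            "returning %d with low confidence", ks[0], ks[0]
        )
        return ks[0]
    candidate = max(supported)
    n = res.consensus[candidate].shape[0]
    tri = res.consensus[candidate][np.triu_indices(n, k=1)]
    ambiguous = float(((tri > 0.1) & (tri < 0.9)).mean())
    if ambiguous > 0.5:
        res.low_confidence = True
        res.chosen_k = ks[0]
        logger.warning(
            "consensus at k=%d is mostly ambiguous (%.0f%% of pairs between "
            "0.1 and 0.9): no supported cluster structure; returning %d with "
            "low confidence", candidate, 100 * ambiguous, ks[0]
        )
        return ks[0]
    res.chosen_k = candidate
    return candidate


def assign_subtype_names(labels: np.ndarray | pd.Series, z: ZMatrix) -> SubtypeLabeling:
    """Name three clusters TCE / EPCE / TASCE by their enriched components.

    Per cluster, the mean z of each component is computed; each subtype name
    goes to the cluster maximizing its criterion score (see
    :data:`NAMING_CRITERIA`). If two criteria point at the same cluster the
    names are assigned greedily in order of score margin and a warning is
    logged.
    """
    labels = pd.Series(np.asarray(labels), index=z.z_values.index, name="cluster")
    clusters = sorted(labels.unique())
    if len(clusters) != 3:
        raise ValueError(f"subtype naming requires exactly 3 clusters, got {len(clusters)}")
    enrichment = z.z_values.groupby(labels).mean()  # clusters x components

    scores = pd.DataFrame(
        {name: enrichment[list(cols)].mean(axis=1) for name, cols in NAMING_CRITERIA.items()}
    )  # clusters x 3 names
    argmaxes = {name: scores[name].idxmax() for name in NAMING_CRITERIA}
    if len(set(argmaxes.values())) == 3:
        cluster_to_name = {cluster: name for name, cluster in argmaxes.items()}
    else:
        logger.warning(
            "naming criteria collide (%s); falling back to greedy assignment by margin", argmaxes
        )
        cluster_to_name = {}
        remaining = dict(scores.items())
        free_clusters = set(clusters)
        while remaining:
            margins = {}
            for name, col in remaining.items():
                avail = col[list(free_clusters)].sort_values(ascending=False)
                margins[name] = (
                    avail.iloc[0] - (avail.iloc[1] if len(avail) > 1 else -np.inf),
                    avail.index[0],
                )
            name = max(margins, key=lambda nm: margins[nm][0])
            cluster = margins[name][1]
            cluster_to_name[cluster] = name
            free_clusters.discard(cluster)
            del remaining[name]
    named = labels.map(cluster_to_name).rename("subtype")
    return SubtypeLabeling(named, cluster_to_name, enrichment)
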