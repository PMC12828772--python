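import numpy as np
import pandas as pd
import pytest

import tmesubtypes as tms
from tmesubtypes.subtyping import NAMING_CRITERIA, pam
from conftest import make_composition, COMPONENTS


def _zmatrix(values: np.ndarray, sample_ids=None) -> tms.ZMatrix:
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=sample_ids, columns=COMPONENTS[: values.shape[1]])
    return tms.ZMatrix(df, df.mean(), df.std(ddof=1), [])


def _planted_blobs(n_per, centers, sd, seed=0):
    """Well-separated 8-d Gaussian blobs as a ZMatrix plus true labels."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(rng.normal(c, sd, size=(n_per, 8)))
        labels += [i] * n_per
    return _zmatrix(np.vstack(rows)), np.array(labels)


class TestZscore:
    def test_values_1_2_3_standardize_to_unit_steps(self):
        # component 0 takes (0.01, 0.02, 0.03); the remainder column absorbs
        # the difference so rows stay exactly on the simplex
        props = np.tile([0.1] * 8, (3, 1))
        props[:, 0] = [0.01, 0.02, 0.03]
        props[:, 7] = 1.0 - props[:, :7].sum(axis=1)
        comp = make_composition(props)
        z = tms.zscore(comp)
        col = z.z_values.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(col, [-1, 0, 1], atol=1e-9)

    def test_constant_column_maps_to_zero_with_flag(self):
        props = np.tile([0.125] * 8, (4, 1))
        props[:, 1] = [0.1, 0.12, 0.14, 0.16]
        props[:, 0] = 0.08
        props[:, 2] = 1 - props[:, [0, 1]].sum(axis=1) - props[:, 3:].sum(axis=1)
        comp = make_composition(props / props.sum(axis=1, keepdims=True))
        z = tms.zscore(comp)
        # the normalization leaves truly constant columns constant
        for name in z.constant_components:
            assert np.allclose(z.z_values[name], 0.0)

    def test_output_columns_standardized(self, default_composition):
        z = tms.zscore(default_composition)
        np.testing.assert_allclose(z.z_values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.z_values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_single_sample_rejected(self):
        comp = make_composition(np.array([[0.125] * 8]))
        with pytest.raises(ValueError, match="2 samples"):
            tms.zscore(comp)


class TestPam:
    def test_recovers_obvious_partition(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        D = np.abs(X - X.T)
        labels = pam(D, 2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equals_n_puts_every_point_alone(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 2))
        D = np.linalg.norm(X[:, None] - X[None], axis=-1)
        labels = pam(D, 5)
        assert len(set(labels)) == 5


class TestConsensusCluster:
    def test_planted_clusters_give_block_consensus_and_perfect_ari(self):
        from sklearn.metrics import adjusted_rand_score

        z, truth = _planted_blobs(20, [np.zeros(8), np.full(8, 8.0), np.full(8, -8.0)], 1.0)
        res = tms.consensus_cluster(z, (2, 4), n_resamples=50, seed=3)
        cons = res.consensus[3]
        same = truth[:, None] == truth[None, :]
        assert cons[same & (np.eye(60) == 0)].min() > 0.95
        assert cons[~same].max() < 0.05
        assert adjusted_rand_score(truth, res.labels[3]) == 1.0

    def test_duplicated_points_always_cocluster(self):
        base = np.array([[0.0] * 8, [5.0] * 8, [-5.0] * 8])
        z = _zmatrix(np.repeat(base, 4, axis=0))
        res = tms.consensus_cluster(z, (3, 3), n_resamples=30, subsample_fraction=0.9, seed=0)
        cons = res.consensus[3]
        for g in range(3):
            block = cons[g * 4 : (g + 1) * 4, g * 4 : (g + 1) * 4]
            np.testing.assert_allclose(block, 1.0)

    def test_same_seed_reproduces_consensus(self):
        z, _ = _planted_blobs(10, [np.zeros(8), np.full(8, 6.0)], 1.0, seed=5)
        a = tms.consensus_cluster(z, (2, 3), n_resamples=25, seed=7)
        b = tms.consensus_cluster(z, (2, 3), n_resamples=25, seed=7)
        for k in a.k_values:
            np.testing.assert_array_equal(a.consensus[k], b.consensus[k])
            np.testing.assert_array_equal(a.labels[k], b.labels[k])

    def test_consensus_matrix_invariants(self):
        z, _ = _planted_blobs(8, [np.zeros(8), np.full(8, 4.0), np.full(8, -4.0)], 1.5)
        res = tms.consensus_cluster(z, (2, 5), n_resamples=40, seed=1)
        for k in res.k_values:
            c = res.consensus[k]
            assert c.min() >= 0 and c.max() <= 1
            np.testing.assert_array_equal(c, c.T)
            np.testing.assert_allclose(np.diag(c), 1.0)
            assert len(np.unique(res.labels[k])) == k

    def test_precondition_violations_rejected(self):
        z, _ = _planted_blobs(5, [np.zeros(8), np.ones(8)], 1.0)
        with pytest.raises(ValueError, match="n_resamples"):
            tms.consensus_cluster(z, (2, 3), n_resamples=5)
        with pytest.raises(ValueError, match="subsample_fraction"):
            tms.consensus_cluster(z, (2, 3), n_resamples=20, subsample_fraction=1.5)


class TestSelectK:
    def test_three_planted_clusters_select_three(self):
        z, _ = _planted_blobs(25, [np.zeros(8), np.full(8, 8.0), np.full(8, -8.0)], 1.0)
        res = tms.consensus_cluster(z, (2, 6), n_resamples=60, seed=2)
        assert tms.select_k(res) == 3
        assert not res.low_confidence

    def test_fixed_policy_ignores_structure(self):
        z, _ = _planted_blobs(25, [np.zeros(8), np.full(8, 8.0)], 1.0)
        res = tms.consensus_cluster(z, (2, 4), n_resamples=30, seed=2)
        assert tms.select_k(res, policy="fixed", fixed_k=3) == 3

    def test_structureless_blob_returns_min_k_with_flag(self):
        rng = np.random.default_rng(9)
        z = _zmatrix(rng.normal(size=(60, 8)))
        res = tms.consensus_cluster(z, (2, 5), n_resamples=60, seed=4)
        k = tms.select_k(res)
        assert k == 2
        assert res.low_confidence


class TestAssignSubtypeNames:
    def test_constructed_enrichment_gives_bijective_naming(self):
        rng = np.random.default_rng(0)
        z_vals = rng.normal(0, 0.1, size=(9, 8))
        cols = {name: COMPONENTS.index(c[0]) for name, c in NAMING_CRITERIA.items()}
        labels = np.repeat([0, 1, 2], 3)
        z_vals[labels == 0, cols["TCE"]] += 3  # cluster 0: T-cell high
        z_vals[labels == 1, cols["EPCE"]] += 3  # cluster 1: epithelial high
        z_vals[labels == 2, cols["TASCE"]] += 3  # cluster 2: stromal high
        naming = tms.assign_subtype_names(labels, _zmatrix(z_vals))
        assert naming.cluster_to_name == {0: "TCE", 1: "EPCE", 2: "TASCE"}

    def test_collision_resolved_greedily_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        z_vals = rng.normal(0, 0.05, size=(9, 8))
        labels = np.repeat([0, 1, 2], 3)
        # cluster 0 maximizes both the T-cell and the epithelial criterion
        z_vals[labels == 0, COMPONENTS.index("CD4_Tcells")] += 3
        z_vals[labels == 0, COMPONENTS.index("CD8_Tcells")] += 3
        z_vals[labels == 0, COMPONENTS.index("uncharacterized")] += 1
        z_vals[labels == 2, COMPONENTS.index("CAFs")] += 3
        with caplog.at_level("WARNING"):
            naming = tms.assign_subtype_names(labels, _zmatrix(z_vals))
        assert sorted(naming.cluster_to_name.values()) == ["EPCE", "TASCE", "TCE"]
        assert any("greedy" in r.message for r in caplog.records)

    def test_wrong_cluster_count_rejected(self):
        z, _ = _planted_blobs(4, [np.zeros(8), np.ones(8)], 0.5)
        with pytest.raises(ValueError, match="3 clusters"):
            tms.assign_subtype_names(np.repeat([0, 1], 4), z)

    def test_planted_subtypes_recovered_by_name(self, default_cohort, default_composition):
        truth = default_cohort[3]
        z = tms.zscore(default_composition)
        res = tms.consensus_cluster(z, (3, 3), n_resamples=100, seed=11)
        naming = tms.assign_subtype_names(res.labels[3], z)
        agreement = (naming.labels == truth.sample_subtype).mean()
        assert agreement >= 0.95


def test_affine_rescaling_of_component_does_not_change_clustering(default_composition):
    """Z-scoring makes clustering invariant to affine rescaling of any raw
    component column (verified through the consensus labels)."""
    comp = default_composition
    z_a = tms.zscore(comp)
    scaled = comp.proportions.copy()
    scaled["CAFs"] = scaled["CAFs"] * 3.0 + 0.05  # affine, breaks the simplex on purpose
    z_b = tms.ZMatrix(
        (scaled - scaled.mean()) / scaled.std(ddof=1), scaled.mean(), scaled.std(ddof=1), []
    )
    sub_a = tms.ZMatrix(z_a.z_values.iloc[:60], None, None, [])
    sub_b = tms.ZMatrix(z_b.z_values.iloc[:60], None, None, [])
    res_a = tms.consensus_cluster(sub_a, (3, 3), n_resamples=40, seed=5)
    res_b = tms.consensus_cluster(sub_b, (3, 3), n_resamples=40, seed=5)
    np.testing.assert_allclose(res_a.consensus[3], res_b.consensus[3], atol=1e-12)
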