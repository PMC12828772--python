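import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

import tmesubtypes as tms
from tmesubtypes.survival import SurvivalError
from conftest import make_clinical


def cox_score_statistic(times, events, group):
    """Score test of a binary Cox covariate at beta = 0 (no ties assumed):
    U(0)^2 / I(0). Equals the two-group log-rank chi-square."""
    order = np.argsort(times)
    times, events, group = times[order], events[order], group[order]
    U = 0.0
    I = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        at_risk = np.arange(len(times)) >= i
        n = at_risk.sum()
        n1 = group[at_risk].sum()
        U += group[i] - n1 / n
        I += (n1 / n) * (1 - n1 / n)
    return U**2 / I


def partial_loglik_binary(beta, times, events, group):
    """Breslow partial log-likelihood for one binary covariate (no ties)."""
    order = np.argsort(times)
    times, events, group = times[order], events[order], group[order]
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        at_risk = np.arange(len(times)) >= i
        ll += beta * group[i] - np.log(np.exp(beta * group[at_risk]).sum())
    return ll


class TestKmEstimate:
    def test_two_subjects_no_censoring_product_limit_by_hand(self):
        clin = make_clinical([1.0, 2.0], [1, 1])
        groups = pd.Series(["TCE", "TCE"], index=clin.data.index)
        curves, _ = tms.km_estimate(clin, groups)
        c = curves["TCE"]
        np.testing.assert_allclose(c.times, [1.0, 2.0])
        np.testing.assert_allclose(c.survival, [0.5, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=50)
        clin = make_clinical(t, np.ones(50, dtype=int))
        curves, _ = tms.km_estimate(clin, pd.Series(["TCE"] * 50, index=clin.data.index))
        c = curves["TCE"]
        empirical = 1.0 - np.searchsorted(np.sort(t), c.times, side="right") / 50
        np.testing.assert_allclose(c.survival, empirical, atol=1e-12)

    def test_censored_only_group_stays_at_one(self):
        clin = make_clinical([5.0, 10.0, 15.0], [0, 0, 0])
        curves, _ = tms.km_estimate(clin, pd.Series(["TCE"] * 3, index=clin.data.index))
        np.testing.assert_allclose(curves["TCE"].survival, 1.0)

    def test_identical_groups_logrank_near_zero(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        clin = make_clinical(t + t, [1, 0, 1, 1, 0] * 2,
                             ids=[f"P{i}" for i in range(10)])
        groups = pd.Series(["TCE"] * 5 + ["EPCE"] * 5, index=clin.data.index)
        _, lr = tms.km_estimate(clin, groups)
        assert lr.statistic == pytest.approx(0.0, abs=1e-9)
        assert lr.p_value > 0.99

    def test_truncation_flag_marks_small_risk_sets(self):
        clin = make_clinical(np.arange(1.0, 11.0), np.ones(10, dtype=int))
        curves, _ = tms.km_estimate(clin, pd.Series(["TCE"] * 10, index=clin.data.index))
        c = curves["TCE"]
        np.testing.assert_array_equal(c.truncated, c.at_risk < 5)
        assert c.truncated.sum() == 4  # at-risk 4, 3, 2, 1


class TestLogrankScoreIdentity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_group_logrank_equals_squared_cox_score(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        group = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(10 / (1 + group), size=n)  # distinct a.s.
        events = (rng.random(n) < 0.7).astype(int)
        if events.sum() < 2:
            events[:2] = 1
        clin = make_clinical(times, events)
        labels = pd.Series(np.where(group > 0, "EPCE", "TCE"), index=clin.data.index)
        _, lr = tms.km_estimate(clin, labels)
        oracle = cox_score_statistic(times, events, group)
        assert lr.statistic == pytest.approx(oracle, abs=1e-6)


class TestCoxFit:
    def test_mirrored_groups_give_null_coefficient(self):
        times = [1.0, 2.0, 3.0, 4.0]
        clin = make_clinical(times + times, [1, 1, 0, 0] * 2,
                             ids=[f"P{i}" for i in range(8)])
        sub = pd.Series(["TCE"] * 4 + ["EPCE"] * 4, index=clin.data.index)
        fit = tms.cox_fit(clin, ["subtype"], subtypes=sub)
        assert fit.terms.loc["subtype_EPCE", "coef"] == pytest.approx(0.0, abs=1e-8)
        assert fit.terms.loc["subtype_EPCE", "hr"] == pytest.approx(1.0, abs=1e-8)

    def test_four_subject_toy_matches_grid_search_mle(self):
        """Interleaved event times (group A at t=1,3; group B at t=2,4) give
        a finite MLE; the fitted coefficient must maximize the (tie-free)
        partial likelihood, checked against 1-d numerical maximization.
        (Fully ordered groups have a monotone likelihood and no finite MLE.)"""
        times = np.array([1.0, 3.0, 2.0, 4.0])
        events = np.array([1, 1, 1, 1])
        group = np.array([0.0, 0.0, 1.0, 1.0])
        clin = make_clinical(times, events)
        sub = pd.Series(np.where(group > 0, "EPCE", "TCE"), index=clin.data.index)
        fit = tms.cox_fit(clin, ["subtype"], subtypes=sub)
        oracle = minimize_scalar(
            lambda b: -partial_loglik_binary(b, times, events, group),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-8},
        ).x
        assert fit.terms.loc["subtype_EPCE", "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_wald_ci_consistent_with_coef_and_se(self, reference):
        cfg = tms.SimulationConfig(n_patients=405, seed=1001)
        _, _, clin, truth = tms.simulate_cohort(cfg, reference)
        fit = tms.cox_fit(clin, ["subtype"], subtypes=truth.patient_subtype)
        t = fit.terms
        np.testing.assert_allclose(
            t["ci_low"], np.exp(t["coef"] - 1.959964 * t["se"]), rtol=1e-6
        )
        np.testing.assert_allclose(
            t["ci_high"], np.exp(t["coef"] + 1.959964 * t["se"]), rtol=1e-6
        )
        assert 0 <= fit.concordance <= 1

    def test_no_events_rejected(self):
        clin = make_clinical([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        sub = pd.Series(["TCE", "TCE", "EPCE", "EPCE"], index=clin.data.index)
        with pytest.raises(SurvivalError, match="no events"):
            tms.cox_fit(clin, ["subtype"], subtypes=sub)

    def test_zero_event_level_flagged_as_non_identifiable(self):
        rng = np.random.default_rng(5)
        n = 60
        times = rng.exponential(20, n)
        sub = pd.Series(["TCE"] * 20 + ["EPCE"] * 20 + ["TASCE"] * 20)
        events = np.where(sub == "TCE", 0, (rng.random(n) < 0.6).astype(int))
        clin = make_clinical(times, events, ids=sub.index.astype(str))
        sub.index = clin.data.index
        try:
            fit = tms.cox_fit(clin, ["subtype"], subtypes=sub)
            assert set(fit.non_identifiable) == {"subtype_EPCE", "subtype_TASCE"}
        except SurvivalError as err:  # full separation may abort the fit instead
            assert "zero-event" in str(err)

    def test_coefficient_bias_shrinks_with_sample_size(self, reference):
        biases = []
        for n in (100, 400, 1600):
            errs = []
            for rep in range(3):
                cfg = tms.SimulationConfig(n_patients=n, seed=9000 + 13 * rep + n)
                _, _, clin, truth = tms.simulate_cohort(cfg, reference)
                fit = tms.cox_fit(clin, ["subtype"], subtypes=truth.patient_subtype)
                if fit.non_identifiable:
                    continue
                errs.append(fit.terms.loc["subtype_TASCE", "coef"] - np.log(10.9))
            biases.append(abs(np.mean(errs)))
        assert biases[-1] < 0.15
        assert biases[-1] <= biases[0] + 0.05


class TestConcordance:
    def test_perfect_and_anti_perfect_ordering(self):
        clin = make_clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        risk = pd.Series([4.0, 3.0, 2.0, 1.0], index=clin.data.index)
        assert tms.concordance_index(risk, clin) == 1.0
        assert tms.concordance_index(-risk, clin) == 0.0

    def test_tied_scores_match_exhaustive_enumeration(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        risk = np.array([2.0, 2.0, 1.0])
        clin = make_clinical(times, events)
        # pairs: (0,1) tied scores -> 0.5; (0,2) concordant; (1,2) concordant
        expected = (0.5 + 1 + 1) / 3
        assert tms.concordance_index(risk, clin) == pytest.approx(expected)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10000
        clin = make_clinical(rng.exponential(10, n), (rng.random(n) < 0.5).astype(int))
        c = tms.concordance_index(pd.Series(rng.normal(size=n), index=clin.data.index), clin)
        assert c == pytest.approx(0.5, abs=0.02)

    def test_no_events_rejected(self):
        clin = make_clinical([1.0, 2.0], [0, 0])
        with pytest.raises(SurvivalError, match="permissible"):
            tms.concordance_index(np.array([1.0, 2.0]), clin)


class TestPhTest:
    def _simulate_ph(self, rng, n=120, flip=False):
        group = (rng.random(n) < 0.5).astype(float)
        if flip:
            # effect reverses sign at the median time: strong PH violation
            u = rng.random(n)
            base = -np.log(u)
            times = np.where(
                base < 0.7, base / np.exp(0.9 * group), 0.7 + (base - 0.7) * np.exp(0.9 * group)
            )
        else:
            times = rng.exponential(1.0 / np.exp(0.8 * group))
        censor = rng.uniform(0, 2.2, n)
        events = (times <= censor).astype(int)
        obs = np.minimum(times, censor) + 1e-6
        clin = make_clinical(obs, events)
        sub = pd.Series(np.where(group > 0, "EPCE", "TCE"), index=clin.data.index)
        return clin, sub

    def test_type_one_error_near_nominal_under_ph(self):
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 200
        for _ in range(reps):
            clin, sub = self._simulate_ph(rng)
            try:
                fit = tms.cox_fit(clin, ["subtype"], subtypes=sub)
            except SurvivalError:
                continue
            per_term, _ = tms.ph_test(fit)
            rejections += per_term["p"].iloc[0] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.04)

    def test_power_against_sign_flipping_effect(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 60
        for _ in range(reps):
            clin, sub = self._simulate_ph(rng, n=150, flip=True)
            fit = tms.cox_fit(clin, ["subtype"], subtypes=sub)
            per_term, _ = tms.ph_test(fit)
            rejections += per_term["p"].iloc[0] < 0.05
        assert rejections / reps >= 0.8

    def test_single_event_rejected(self):
        clin = make_clinical([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        sub = pd.Series(["TCE", "TCE", "EPCE", "EPCE"], index=clin.data.index)
        fit = tms.cox_fit(clin, ["subtype"], subtypes=sub)
        fit.n_events = 1
        with pytest.raises(SurvivalError, match="2 events"):
            tms.ph_test(fit)


class TestModelComparison:
    def test_identical_covariate_sets_identical_concordance(self, reference):
        cfg = tms.SimulationConfig(n_patients=300, seed=31)
        _, _, clin, truth = tms.simulate_cohort(cfg, reference)
        table = tms.model_comparison(
            clin, {"a": ["gleason"], "b": ["gleason"]}, subtypes=truth.patient_subtype
        )
        assert table.loc["a", "concordance"] == table.loc["b", "concordance"]

    def test_true_subtype_covariate_increases_concordance(self, reference):
        cfg = tms.SimulationConfig(n_patients=1000, seed=33)
        _, _, clin, truth = tms.simulate_cohort(cfg, reference)
        table = tms.model_comparison(
            clin,
            {"gleason": ["gleason"], "gleason_subtype": ["gleason", "subtype"]},
            subtypes=truth.patient_subtype,
        )
        assert (
            table.loc["gleason_subtype", "concordance"]
            > table.loc["gleason", "concordance"]
        )

    def test_noise_covariate_barely_moves_concordance(self, reference):
        """Replacing true subtype labels by a shuffled (pure noise) copy
        changes the Gleason-model concordance by less than 0.02."""
        cfg = tms.SimulationConfig(n_patients=1000, seed=34)
        _, _, clin, truth = tms.simulate_cohort(cfg, reference)
        rng = np.random.default_rng(0)
        deltas = []
        for _ in range(3):
            noise = pd.Series(
                rng.permutation(truth.patient_subtype.to_numpy()),
                index=truth.patient_subtype.index,
            )
            table = tms.model_comparison(
                clin,
                {"gleason": ["gleason"], "gleason_noise": ["gleason", "subtype"]},
                subtypes=noise,
            )
            deltas.append(
                abs(table.loc["gleason_noise", "concordance"]
                    - table.loc["gleason", "concordance"])
            )
        assert np.mean(deltas) < 0.02
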