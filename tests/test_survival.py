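"""Survival statistics: KM, log-rank, Cox, discrimination, agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import concordance_index as lifelines_cindex

from tilquant.errors import DegenerateInputError, FitError, ParameterError
from tilquant.survival import (
    bland_altman,
    cox_fit,
    harrell_cindex,
    icc,
    integrated_auc,
    kaplan_meier,
    likelihood_ratio_test,
    linear_by_linear,
    logrank_test,
    mann_whitney_u,
    max_candidate_predictors,
    pearson_chi_square,
    reverse_km_median_followup,
    schoenfeld_ph_test,
    screen_candidates,
    stepwise_aic,
)
from tilquant.synth import CohortSpec, generate_survival_cohort


class TestKaplanMeier:
    def test_product_limit_matches_hand_computation(self):
        kmf = kaplan_meier([1, 2, 3], [1, 1, 1])
        s = kmf.survival_function_["KM_estimate"]
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[2.0] == pytest.approx(1 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        kmf = kaplan_meier([5, 7, 9], [0, 0, 0])
        assert (kmf.survival_function_["KM_estimate"] == 1.0).all()

    def test_curve_non_increasing_from_one(self, effect_cohort):
        kmf = kaplan_meier(effect_cohort["time"], effect_cohort["event"])
        s = kmf.survival_function_["KM_estimate"].to_numpy()
        assert s[0] <= 1.0 + 1e-12
        assert (np.diff(s) <= 1e-12).all()


class TestReverseKm:
    def test_hand_example(self):
        # flipping the indicator, the only "event" is the censoring at t=4
        median, _ = reverse_km_median_followup([2, 4, 6], [1, 0, 1])
        assert median == pytest.approx(4.0)

    def test_no_censoring_gives_undefined_median_signal(self):
        median, _ = reverse_km_median_followup([1, 2, 3], [1, 1, 1])
        assert np.isinf(median)

    def test_all_censored_at_t_gives_t(self):
        median, _ = reverse_km_median_followup([8.0, 8.0, 8.0], [0, 0, 0])
        assert median == pytest.approx(8.0)


class TestLogrank:
    def test_identical_groups_have_zero_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        groups = ["a"] * 4 + ["b"] * 4
        stat, p, df = logrank_test(groups, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_two_subject_toy_matches_hand_bookkeeping(self):
        # at t=1 both at risk, event in group a: O-E = 0.5, V = 0.25 -> chi2 = 1
        stat, p, _ = logrank_test(["a", "b"], [1, 2], [1, 1])
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_strong_split_detected(self, effect_cohort):
        groups = (effect_cohort["score"] > 50).map({True: "high", False: "low"})
        stat, p, _ = logrank_test(groups, effect_cohort["time"], effect_cohort["event"])
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            logrank_test(["a", "a"], [1, 2], [1, 1])


class TestCoxFit:
    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "time": [1, 2, 3, 4],
                           "event": [0, 0, 0, 0]})
        with pytest.raises(FitError):
            cox_fit(df, ["x"])

    def test_constant_covariate_rejected(self, null_cohort):
        df = null_cohort.assign(flat=1.0)
        with pytest.raises(FitError):
            cox_fit(df, ["flat"])

    def test_aic_identity(self, effect_cohort):
        df = effect_cohort.assign(high=(effect_cohort["score"] > 50).astype(float))
        fit = cox_fit(df, ["high"])
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.k)

    def test_confidence_interval_brackets_hazard_ratio(self, effect_cohort):
        df = effect_cohort.assign(high=(effect_cohort["score"] > 50).astype(float))
        fit = cox_fit(df, ["high"])
        hr, (lo, hi), p = fit.hazard_ratio("high")
        assert lo < hr < hi
        assert hr < 1.0  # protective effect
        assert p < 0.01


@pytest.fixture(scope="module")
def cohort_with_noise():
    return generate_survival_cohort(
        CohortSpec(
            n_subjects=400,
            hazard_ratio_high_vs_low=1.0,
            covariate_effects={"x": np.log(3.0), "n1": 0.0, "n2": 0.0, "n3": 0.0},
            seed=8,
        )
    )


class TestScreeningAndStepwise:

    def test_strong_effect_always_screened_in(self, cohort_with_noise):
        kept = screen_candidates(cohort_with_noise, ["x", "n1", "n2", "n3"])
        assert "x" in kept

    def test_alpha_one_keeps_everything(self, cohort_with_noise):
        kept = screen_candidates(cohort_with_noise, ["x", "n1"], alpha=1.0)
        assert kept == ["x", "n1"]

    def test_alpha_zero_keeps_nothing(self, cohort_with_noise):
        assert screen_candidates(cohort_with_noise, ["x", "n1"], alpha=0.0) == []

    def test_stepwise_keeps_true_effect_and_improves_aic(self, cohort_with_noise):
        best = stepwise_aic(cohort_with_noise, ["x", "n1", "n2", "n3"])
        full = cox_fit(cohort_with_noise, ["x", "n1", "n2", "n3"])
        assert "x" in best.covariates
        assert best.aic <= full.aic
        # search invariant: no visited model beats the returned one
        assert best.aic <= best.search_trace["aic"].min() + 1e-9

    def test_single_strong_candidate_returned_as_is(self, cohort_with_noise):
        best = stepwise_aic(cohort_with_noise, ["x"])
        assert best.covariates == ["x"]

    def test_empty_candidates_rejected(self, cohort_with_noise):
        with pytest.raises(ParameterError):
            stepwise_aic(cohort_with_noise, [])


class TestConcordance:
    def test_perfect_ranking_gives_one(self):
        c, _ = harrell_cindex([3, 2, 1], [1, 2, 3], [1, 1, 1], n_boot=0)
        assert c == 1.0

    def test_constant_risk_gives_half(self):
        c, _ = harrell_cindex([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1], n_boot=0)
        assert c == 0.5

    def test_reversed_ranking_gives_zero(self):
        c, _ = harrell_cindex([1, 2, 3], [1, 2, 3], [1, 1, 1], n_boot=0)
        assert c == 0.0

    def test_negation_flips_concordance(self, effect_cohort):
        risk = -effect_cohort["score"].to_numpy()
        t, e = effect_cohort["time"], effect_cohort["event"]
        c_pos, _ = harrell_cindex(risk, t, e, n_boot=0)
        c_neg, _ = harrell_cindex(-risk, t, e, n_boot=0)
        assert c_pos + c_neg == pytest.approx(1.0)

    def test_matches_lifelines_with_censoring_and_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = np.round(rng.exponential(10, 60)) + 1
            e = rng.integers(0, 2, 60)
            risk = rng.normal(size=60)
            mine, _ = harrell_cindex(risk, t, e, n_boot=0)
            # lifelines scores predicted survival times: negate the risk
            assert mine == pytest.approx(lifelines_cindex(t, -risk, e))

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            harrell_cindex([1, 2], [5, 5], [0, 0], n_boot=0)


class TestIntegratedAuc:
    def test_perfect_ranking_on_all_event_cohort(self):
        t = np.arange(1.0, 41.0)
        iauc, _ = integrated_auc(-t, t, np.ones(40, int), n_boot=10, seed=0)
        assert iauc >= 0.99

    def test_constant_risk_is_random_prediction(self):
        t = np.arange(1.0, 41.0)
        iauc, _ = integrated_auc(np.zeros(40), t, np.ones(40, int), n_boot=10, seed=0)
        assert iauc == pytest.approx(0.5)

    def test_fixed_seed_reproduces_bootstrap_interval(self, effect_cohort):
        risk = -effect_cohort["score"].to_numpy()
        args = (risk, effect_cohort["time"], effect_cohort["event"])
        a = integrated_auc(*args, n_boot=50, seed=9)
        b = integrated_auc(*args, n_boot=50, seed=9)
        assert a == b

    def test_degenerate_followup_rejected(self):
        with pytest.raises(DegenerateInputError):
            integrated_auc([1, 2, 3], [5, 5, 5], [1, 1, 1], n_boot=5)


@pytest.fixture(scope="module")
def fits():
    df = generate_survival_cohort(
        CohortSpec(n_subjects=250, covariate_effects={"a": 0.8, "z": 0.0}, seed=6)
    )
    return cox_fit(df, ["a"]), cox_fit(df, ["a", "z"])


class TestModelComparison:

    def test_identical_models_give_zero_statistic(self, fits):
        nested, _ = fits
        lam, df, p = likelihood_ratio_test(nested, nested)
        assert (lam, df, p) == (0.0, 0, 1.0)

    def test_statistic_is_twice_delta_loglik(self, fits):
        nested, full = fits
        lam, df, p = likelihood_ratio_test(nested, full)
        assert lam == pytest.approx(
            2 * (full.log_likelihood - nested.log_likelihood)
        )
        assert df == 1
        assert 0 <= p <= 1

    def test_non_nested_models_rejected(self, fits):
        nested, full = fits
        with pytest.raises(ParameterError):
            likelihood_ratio_test(full, nested)


@pytest.fixture(scope="module")
def ph_fit():
    df = generate_survival_cohort(
        CohortSpec(n_subjects=200, covariate_effects={"a": 0.7, "b": 0.0}, seed=5)
    )
    df["high"] = (df["score"] > 50).astype(float)
    return cox_fit(df, ["a", "b", "high"])


class TestSchoenfeld:

    def test_per_covariate_matches_lifelines_rank_transform(self, ph_fit):
        fit = ph_fit
        per, global_p = schoenfeld_ph_test(fit)
        ref = proportional_hazard_test(
            fit.model, fit.data[fit.covariates + ["time", "event"]],
            time_transform="rank",
        ).summary
        for name in fit.covariates:
            assert per.loc[name, "chi2"] == pytest.approx(
                float(ref.loc[name, "test_statistic"]), rel=1e-6
            )
        assert 0 <= global_p <= 1

    def test_residuals_sum_to_zero(self, ph_fit):
        fit = ph_fit
        resid = fit.model.compute_residuals(
            fit.data[fit.covariates + ["time", "event"]], kind="schoenfeld"
        )
        # zero up to the partial-likelihood solver tolerance
        assert np.allclose(resid[fit.covariates].sum(axis=0), 0.0, atol=1e-3)

    def test_proportional_data_rarely_rejected(self):
        rejected = 0
        for seed in range(20):
            df = generate_survival_cohort(
                CohortSpec(n_subjects=150, covariate_effects={"a": 0.7},
                           seed=300 + seed)
            )
            _, p = schoenfeld_ph_test(cox_fit(df, ["a"]))
            rejected += p < 0.05
        assert rejected <= 4


class TestContingency:
    def test_uniform_table_has_zero_statistic(self):
        chi2, df, p = pearson_chi_square([[5, 5], [5, 5]])
        assert chi2 == pytest.approx(0.0)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi_square([[0, 0], [3, 4]])

    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=2, max_size=3),
            min_size=2, max_size=3,
        ).filter(
            lambda rows: len({len(r) for r in rows}) == 1
            and all(any(r) for r in rows)
            and all(any(col) for col in zip(*rows))
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_sum(self, rows):
        obs = np.array(rows, dtype=float)
        chi2, df, _ = pearson_chi_square(rows)
        n = obs.sum()
        brute = 0.0
        for i in range(obs.shape[0]):
            for j in range(obs.shape[1]):
                e = obs[i].sum() * obs[:, j].sum() / n
                brute += (obs[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(brute)
        assert df == (obs.shape[0] - 1) * (obs.shape[1] - 1)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(1, 1, size=25)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2)


class TestLinearByLinear:
    def test_perfectly_monotone_two_by_two(self):
        m2, p = linear_by_linear([[10, 0], [0, 10]])
        assert m2 == pytest.approx(19.0)
        assert p == pytest.approx(1.307e-5, rel=1e-3)

    def test_independent_table_near_zero(self):
        m2, p = linear_by_linear([[20, 20], [10, 10]])
        assert m2 == pytest.approx(0.0, abs=1e-10)

    def test_reversing_order_leaves_statistic_unchanged(self):
        table = [[8, 3, 1], [4, 6, 5], [1, 2, 9]]
        m2a, _ = linear_by_linear(table)
        m2b, _ = linear_by_linear(table[::-1])
        assert m2a == pytest.approx(m2b)

    def test_zero_score_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            linear_by_linear([[5, 5]])


class TestAgreement:
    def test_identical_vectors_have_zero_bias_and_loa(self):
        res = bland_altman([3, 4, 5], [3, 4, 5])
        assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        manual = np.array([10.0, 20.0, 30.0])
        res = bland_altman(manual, manual + 2.0)
        assert res.bias == pytest.approx(-2.0)
        assert res.loa_high - res.loa_low == pytest.approx(0.0)

    def test_loa_uses_sample_sd(self):
        res = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96)

    def test_icc_identical_vectors_is_one(self):
        val, _ = icc([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert val == 1.0

    def test_icc_high_when_noise_small(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(50, 500, 60)
        a = m + rng.normal(0, 5, 60)
        val, (lo, hi) = icc(m, a)
        assert val >= 0.9
        # the reported interval is rounded to two decimals
        assert lo - 0.005 <= val <= hi + 0.005

    def test_icc_near_zero_for_independent_vectors(self):
        rng = np.random.default_rng(4)
        vals = [icc(rng.normal(size=40), rng.normal(size=40))[0] for _ in range(10)]
        assert abs(np.mean(vals)) < 0.25


class TestEventsPerPredictor:
    @pytest.mark.parametrize("n_events,expected", [(72, 7), (10, 1), (9, 0), (0, 0)])
    def test_floor_rule(self, n_events, expected):
        assert max_candidate_predictors(n_events) == expected

    def test_bad_epp_rejected(self):
        with pytest.raises(ParameterError):
            max_candidate_predictors(50, epp=0)
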