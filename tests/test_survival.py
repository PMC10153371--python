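import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from scipy.optimize import minimize_scalar

from glioprog import (CohortGeneratorConfig, SurvivalData, fit_cox,
                      fit_multivariate, generate_cohort, km_estimate,
                      logrank_test, quartile_stratify, screen_pvalues,
                      univariate_screen)
from glioprog.survival import (CollinearityError, ConvergenceError,
                               _numeric_feature)

from conftest import NO_MISSING, make_table


def brute_force_cox_beta(x, time, event):
    """1-D partial-likelihood maximization written out directly
    (untied times), independent of the package implementation."""
    def neg_loglik(beta):
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return -ll
    res = minimize_scalar(neg_loglik, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestFitCox:
    def test_exchangeable_binary_covariate_gives_null_beta(self):
        time = np.array([3, 5, 8, 11, 3, 5, 8, 11], float)
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1], bool)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        fit = fit_cox(x[:, None], SurvivalData(time, event))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_partial_likelihood(self):
        time = np.array([2, 5, 7, 11, 13, 17], float)
        event = np.array([1, 1, 1, 0, 1, 1], bool)
        x = np.array([1, 0, 1, 0, 0, 1], float)
        fit = fit_cox(x[:, None], SurvivalData(time, event))
        assert abs(fit.beta[0]
                   - brute_force_cox_beta(x, time, event)) < 1e-6

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(0)
        time = rng.permutation(np.arange(1, 41)).astype(float)
        event = rng.random(40) < 0.7
        x = rng.normal(size=(40, 2))
        sv = SurvivalData(time, event)
        efron = fit_cox(x, sv, ties="efron")
        breslow = fit_cox(x, sv, ties="breslow")
        np.testing.assert_allclose(efron.beta, breslow.beta, atol=1e-9)
        np.testing.assert_allclose(efron.loglik, breslow.loglik, atol=1e-9)

    def test_matches_lifelines_with_heavy_ties(self):
        rng = np.random.default_rng(1)
        n = 250
        x = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(np.exp(-(0.4 * x[:, 0])), n) * 20)
        e = rng.random(n) < 0.8
        fit = fit_cox(x, SurvivalData(t, e), names=["a", "b"])
        df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "t": t,
                           "e": e.astype(int)})
        ll = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, ll.params_.values, atol=1e-4)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values,
                                   atol=1e-4)

    def test_ci_brackets_hr_and_wald_p_consistent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 1))
        t = np.ceil(rng.exponential(np.exp(-0.5 * x[:, 0])) * 50)
        fit = fit_cox(x, SurvivalData(t, np.ones(100, bool)))
        assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]
        assert 0 <= fit.p[0] <= 1

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(np.ones((5, 1)), SurvivalData(
                np.arange(1.0, 6.0), np.zeros(5, bool)))

    def test_perfect_separation_diagnosed(self):
        # covariate orders time perfectly -> monotone likelihood
        time = np.arange(1.0, 13.0)
        x = -time
        with pytest.raises(ConvergenceError):
            fit_cox(x[:, None], SurvivalData(time, np.ones(12, bool)))


class TestScreen:
    def test_vacuous_alpha_retains_all_fitable(self, clean_cohort):
        _, table, _ = clean_cohort
        surv = SurvivalData(table.df["os_days"].to_numpy(float),
                            table.df["os_event"].astype(bool).to_numpy())
        feats = ["age_at_surgery", "wbc", "platelets"]
        kept, fits = univariate_screen(table, feats, surv, alpha=1.0)
        assert kept == feats and set(fits) == set(feats)

    def test_zero_variance_feature_skipped_with_warning(self, clean_cohort):
        _, table, _ = clean_cohort
        t = table.copy()
        t.df["flat"] = 1.0
        t.schema["flat"] = ("numeric", None)
        surv = SurvivalData(t.df["os_days"].to_numpy(float),
                            t.df["os_event"].astype(bool).to_numpy())
        with pytest.warns(UserWarning, match="flat"):
            kept, fits = univariate_screen(t, ["flat", "wbc"], surv)
        assert "flat" not in fits

    def test_pvalue_gate_is_strict(self):
        assert screen_pvalues([0.049, 0.05, 0.051]).tolist() == [0]

    def test_single_feature_multivariate_reduces_to_univariate(
            self, clean_cohort):
        _, table, _ = clean_cohort
        surv = SurvivalData(table.df["os_days"].to_numpy(float),
                            table.df["os_event"].astype(bool).to_numpy())
        multi = fit_multivariate(table, ["wbc"], surv)
        uni = fit_cox(_numeric_feature(table, "wbc").to_numpy()[:, None],
                      surv, names=["wbc"])
        assert multi.beta[0] == pytest.approx(uni.beta[0], abs=1e-9)

    def test_duplicated_covariates_raise_collinearity(self, clean_cohort):
        _, table, _ = clean_cohort
        t = table.copy()
        t.df["wbc_copy"] = t.df["wbc"]
        t.schema["wbc_copy"] = ("numeric", None)
        surv = SurvivalData(t.df["os_days"].to_numpy(float),
                            t.df["os_event"].astype(bool).to_numpy())
        with pytest.raises(CollinearityError, match="wbc"):
            fit_multivariate(t, ["wbc", "wbc_copy"], surv)


class TestQuartileStratify:
    def test_exact_quartiles_small(self):
        g = quartile_stratify(np.arange(1.0, 9.0), ids=np.arange(1, 9))
        assert g.lo_ids == [1, 2] and g.hi_ids == [7, 8]

    def test_exact_quartiles_1_to_100(self):
        g = quartile_stratify(np.arange(1.0, 101.0))
        assert g.n_lo == 25 and g.n_hi == 25

    def test_boundary_ties_all_join_hi(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 8, 8, 8, 8], float)
        g = quartile_stratify(values)
        # type-7 Q3 of this 12-value fixture is exactly 8
        assert g.q3 == pytest.approx(8.0)
        assert g.n_hi == 5          # every tied 8 included
        assert g.n_lo == 3

    def test_missing_excluded(self):
        values = np.r_[np.arange(1.0, 9.0), np.nan, np.nan]
        g = quartile_stratify(values)
        assert set(g.lo_ids) == {0, 1} and set(g.hi_ids) == {6, 7}

    def test_constant_and_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            quartile_stratify(np.ones(20))
        with pytest.raises(ValueError):
            quartile_stratify(np.arange(5.0))


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        km = km_estimate(SurvivalData([5, 9, 13.0], [False] * 3))
        assert km.event_times.size == 0
        assert np.isnan(km.median)
        assert km.survival_at([1, 10, 100]).tolist() == [1, 1, 1]

    def test_hand_product_limit_fixture(self):
        km = km_estimate(SurvivalData([1, 2, 3, 4.0],
                                      [True, True, False, True]))
        np.testing.assert_allclose(km.survival, [0.75, 0.50, 0.00])
        np.testing.assert_array_equal(km.at_risk, [4, 3, 1])
        assert km.median == 2.0

    def test_doubling_subjects_leaves_curve_unchanged(self):
        t = np.array([3, 6, 6, 10, 14.0])
        e = np.array([1, 1, 0, 1, 0], bool)
        km1 = km_estimate(SurvivalData(t, e))
        km2 = km_estimate(SurvivalData(np.r_[t, t], np.r_[e, e]))
        np.testing.assert_allclose(km1.survival, km2.survival)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        t = np.ceil(rng.exponential(100, 60))
        e = rng.random(60) < 0.7
        perm = rng.permutation(60)
        km1 = km_estimate(SurvivalData(t, e))
        km2 = km_estimate(SurvivalData(t[perm], e[perm]))
        np.testing.assert_array_equal(km1.survival, km2.survival)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(5)
        t = np.ceil(rng.exponential(100, 200))
        e = rng.random(200) < 0.6
        km = km_estimate(SurvivalData(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ours = km.survival_at(km.event_times)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestLogRank:
    def test_identical_groups_null(self):
        sv = SurvivalData([1, 2, 3, 4.0], [1, 1, 0, 1])
        res = logrank_test(sv, sv)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_single_event_time(self):
        # one event at t=1: O1=1, E1 = 1*2/4, V = 1*(2/4)*(2/4)*(3/3)
        a = SurvivalData([1, 2.0], [True, False])
        b = SurvivalData([1, 3.0], [False, False])
        res = logrank_test(a, b)
        o_minus_e, v = 1 - 0.5, 0.25
        assert res.statistic == pytest.approx(o_minus_e ** 2 / v, abs=1e-9)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(6)
        a = SurvivalData(np.ceil(rng.exponential(80, 50)),
                         rng.random(50) < 0.7)
        b = SurvivalData(np.ceil(rng.exponential(120, 50)),
                         rng.random(50) < 0.7)
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(7)
        a = SurvivalData(np.ceil(rng.exponential(80, 80)),
                         rng.random(80) < 0.7)
        b = SurvivalData(np.ceil(rng.exponential(140, 70)),
                         rng.random(70) < 0.7)
        res = logrank_test(a, b)
        ll = ll_logrank(a.time, b.time, a.event, b.event)
        assert res.statistic == pytest.approx(ll.test_statistic, abs=1e-8)
        assert res.p == pytest.approx(ll.p_value, abs=1e-10)

    def test_no_events_undefined(self):
        with pytest.raises(ValueError):
            logrank_test(SurvivalData([1.0], [False]),
                         SurvivalData([2.0], [False]))

    def test_power_under_strong_wbc_effect(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = CohortGeneratorConfig(
                n=250, seed=5000 + rep, beta_wbc=0.12,
                missingness=NO_MISSING)
            table, _ = generate_cohort(cfg)
            sv = SurvivalData(
                table.df["os_days"].to_numpy(float),
                table.df["os_event"].astype(bool).to_numpy())
            g = quartile_stratify(table.df["wbc"].to_numpy(float))
            if logrank_test(sv.subset(g.lo_ids),
                            sv.subset(g.hi_ids)).p < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep
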