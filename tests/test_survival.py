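"""Log-rank, cutpoint search, KM, Cox, stepwise AIC and time-dependent ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from deltarad.survival import (
    cox_fit,
    cox_partial_loglik,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    risk_score,
    stepwise_aic,
    time_dependent_auroc,
    univariate_screen,
    vif_screen,
)
from deltarad.synthetic import generate_survival

from conftest import survival_arrays


# 6-patient worked example; O-E and V enumerated by hand over risk sets:
# group A: 1(event), 3(event), 5(censored); B: 2(event), 4(censored), 6(event)
# t=1: n=6, n1=3, d=1 in A -> O-E 0.5,  V 0.25
# t=2: n=5, n1=2, d=1 in B -> O-E -0.4, V 0.24
# t=3: n=4, n1=2, d=1 in A -> O-E 0.5,  V 0.25
# t=6: n=1 risk set, variance term vanishes
HAND_TIMES = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
HAND_EVENTS = np.array([1, 1, 0, 1, 0, 1])
HAND_GROUPS = np.array([1, 1, 1, 0, 0, 0])
HAND_OME, HAND_V = 0.6, 0.74


class TestLogrank:
    def test_hand_computed_six_patient_example(self):
        res = logrank_test(HAND_GROUPS, HAND_TIMES, HAND_EVENTS)
        assert res.observed_minus_expected == pytest.approx(HAND_OME, abs=1e-12)
        assert res.variance == pytest.approx(HAND_V, abs=1e-12)
        assert res.chi2 == pytest.approx(HAND_OME**2 / HAND_V, abs=1e-12)

    def test_identical_groups_give_zero_statistic(self):
        # each survival time duplicated across arms: O-E vanishes exactly
        t = np.r_[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = np.ones(6, int)
        g = np.r_[np.ones(3), np.zeros(3)]
        res = logrank_test(g, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_lifelines_on_tied_data(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.integers(1, 15, 60).astype(float)  # heavy ties
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60)
        if g.sum() in (0, 60):
            g[0] = 1 - g[0]
        ours = logrank_test(g, t, e)
        ref = ll_logrank(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert ours.chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert ours.p == pytest.approx(ref.p_value, abs=1e-9)

    def test_no_events_anywhere(self):
        res = logrank_test([0, 0, 1, 1], [1, 2, 3, 4], [0, 0, 0, 0])
        assert res.chi2 == 0.0 and res.p == 1.0


def brute_force_cutpoint(marker, time, event, min_group_frac):
    """Direct enumeration oracle: log-rank at every admissible midpoint."""
    n = len(marker)
    distinct = np.unique(marker)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2
        g = marker > cut
        if g.sum() < min_group_frac * n or (~g).sum() < min_group_frac * n:
            continue
        res = logrank_test(g, time, event)
        key = (res.p, cut)
        if best is None or key < best[0]:
            best = (key, cut, res)
    return best


class TestOptimalCutpoint:
    def test_equals_brute_force_enumeration(self, rng):
        for _ in range(5):
            n = 30
            marker = rng.normal(size=n)
            t = rng.exponential(10, n) + 0.1
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            ours = optimal_cutpoint(marker, t, e, 0.1)
            _, cut, res = brute_force_cutpoint(marker, t, e, 0.1)
            assert ours.cutoff == pytest.approx(cut, abs=1e-12)
            assert ours.logrank_chi2 == pytest.approx(res.chi2, abs=1e-9)

    def test_separable_marker_found(self, rng):
        # low marker <-> long survival, clean separation at 0.5
        marker = np.r_[np.zeros(15), np.ones(15)]
        t = np.r_[rng.uniform(50, 60, 15), rng.uniform(1, 5, 15)]
        e = np.ones(30, int)
        res = optimal_cutpoint(marker, t, e)
        assert res.cutoff == pytest.approx(0.5)
        assert res.p < 1e-6
        assert res.group_sizes == (15, 15)

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(np.ones(20), np.arange(1, 21.0), np.ones(20, int))

    def test_group_size_floor_respected(self, rng):
        marker = np.r_[0.0, np.ones(19)]  # only split is 1-vs-19
        t, e = np.arange(1, 21.0), np.ones(20, int)
        with pytest.raises(ValueError, match="group-size"):
            optimal_cutpoint(marker, t, e, min_group_frac=0.2)

    def test_permutation_p_exceeds_raw_p(self, rng):
        marker = rng.normal(size=40)
        t = rng.exponential(10, 40) + 0.1
        e = np.ones(40, int)
        res = optimal_cutpoint(marker, t, e, n_permutations=99, rng=rng)
        assert res.permutation_p >= res.p  # selection-adjusted


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert len(km.times) == 0
        assert km.survival_at([0.5, 5.0]).tolist() == [1.0, 1.0]
        assert np.isnan(km.median)

    def test_all_events_is_ecdf_complement(self, rng):
        t = np.sort(rng.uniform(1, 10, 25))
        km = km_estimate(t, np.ones(25, int))
        for q in [2.0, 5.0, 8.0]:
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_hand_computed_censored_example(self):
        # times 1(e) 2(c) 3(e) 4(e): S = .75, .375, 0; Greenwood by hand
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
        np.testing.assert_allclose(km.times, [1.0, 3.0, 4.0])
        np.testing.assert_allclose(km.survival, [0.75, 0.375, 0.0])
        assert km.variance[0] == pytest.approx(0.75**2 / 12)
        assert km.variance[1] == pytest.approx(0.375**2 * (1 / 12 + 1 / 2))
        assert km.median == 3.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 80) + 0.1
        e = rng.integers(0, 2, 80)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0.1, t.max(), 40)
        ref = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(km.survival_at(grid), ref, atol=1e-12)

    def test_left_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(2.0, left=True) == pytest.approx(2 / 3)


class TestCox:
    def test_hr_identity_and_partial_likelihood_maximum(self):
        # two patients per arm; grid search confirms the fitted maximum
        x = pd.DataFrame({"g": [0.0, 0.0, 1.0, 1.0]})
        t = np.array([4.0, 6.0, 1.0, 3.0])
        e = np.array([1, 1, 1, 1])
        fit = cox_fit(x, t, e)
        coef = fit.summary.loc["g", "coef"]
        assert fit.summary.loc["g", "hr"] == pytest.approx(np.exp(coef), rel=1e-12)
        ll_hat = cox_partial_loglik([coef], x.to_numpy(), t, e)
        assert ll_hat == pytest.approx(fit.log_likelihood, abs=1e-6)
        grid = np.linspace(coef - 2, coef + 2, 401)
        lls = [cox_partial_loglik([b], x.to_numpy(), t, e) for b in grid]
        assert ll_hat >= max(lls) - 1e-6
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2)

    def test_efron_loglik_matches_lifelines_on_tied_data(self, rng):
        x = pd.DataFrame({"z": rng.normal(size=50)})
        t = rng.integers(1, 10, 50).astype(float)
        e = rng.integers(0, 2, 50)
        e[:5] = 1
        fit = cox_fit(x, t, e)
        ll = cox_partial_loglik(fit.summary["coef"].to_numpy(), x.to_numpy(), t, e)
        assert ll == pytest.approx(fit.log_likelihood, abs=1e-6)

    def test_null_hazard_ratio_recovered(self, rng):
        recs = [generate_survival(0.0, 0.05, 100.0, rng) for _ in range(300)]
        t, e = survival_arrays(recs)
        x = pd.DataFrame({"g": rng.integers(0, 2, 300).astype(float)})
        fit = cox_fit(x, t, e)
        lo, hi = fit.summary.loc["g", ["ci_lower", "ci_upper"]]
        assert lo < 1.0 < hi

    def test_degenerate_designs_rejected(self):
        t, e = np.arange(1, 11.0), np.ones(10, int)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"c": np.ones(10)}), t, e)
        few = np.r_[np.ones(2, int), np.zeros(8, int)]
        with pytest.raises(ValueError, match="events"):
            cox_fit(pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5))), t, few)


class TestScreens:
    def test_univariate_empty_table(self):
        report, selected = univariate_screen(
            pd.DataFrame(index=range(10)), np.arange(1, 11.0), np.ones(10, int)
        )
        assert selected == [] and report.empty

    def test_univariate_power_on_true_signal(self, rng):
        g = np.r_[np.zeros(100), np.ones(100)]
        recs = [generate_survival(np.log(4.0) * gi, 0.03, 200.0, rng) for gi in g]
        t, e = survival_arrays(recs)
        feats = pd.DataFrame({"true": g, "noise": rng.normal(size=200)})
        report, selected = univariate_screen(feats, t, e)
        assert "true" in selected

    def test_vif_orthogonal_is_one(self):
        # exactly mutually orthogonal, zero-mean contrast columns
        base = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        x = pd.DataFrame(np.tile(base, (5, 1)), columns=list("abc"))
        v = vif_screen(x)
        np.testing.assert_allclose(v["vif"], 1.0, atol=1e-12)
        assert not v["flagged"].any()

    def test_vif_duplicate_column_infinite(self, rng):
        a = rng.normal(size=25)
        v = vif_screen(pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=25)}))
        assert np.isinf(v.loc["a", "vif"]) and v.loc["a", "flagged"]

    def test_vif_matches_ols_r2_oracle(self, rng):
        import statsmodels.api as sm

        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        X["c"] += 0.8 * X["a"]
        ours = vif_screen(X)
        for j, col in enumerate(X.columns):
            others = sm.add_constant(X.drop(columns=col))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert ours.loc[col, "vif"] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestStepwise:
    def test_empty_candidates_null_model(self):
        res = stepwise_aic(pd.DataFrame(index=range(12)), np.arange(1, 13.0), np.ones(12, int))
        assert res.selected == ()
        assert res.fit.summary.empty

    def test_aic_monotone_and_true_predictor_kept(self, rng):
        g = rng.integers(0, 2, 150).astype(float)
        recs = [generate_survival(1.5 * gi, 0.03, 100.0, rng) for gi in g]
        t, e = survival_arrays(recs)
        cand = pd.DataFrame(
            {"true": g, **{f"n{i}": rng.integers(0, 2, 150).astype(float) for i in range(4)}}
        )
        res = stepwise_aic(cand, t, e)
        assert "true" in res.selected
        aics = [a for _, _, a in res.path]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_within_two_of_best_subset_oracle(self, rng):
        g = rng.integers(0, 2, 80).astype(float)
        recs = [generate_survival(1.2 * gi, 0.04, 80.0, rng) for gi in g]
        t, e = survival_arrays(recs)
        cand = pd.DataFrame(
            {"true": g, **{f"n{i}": rng.normal(size=80) for i in range(5)}}
        )
        res = stepwise_aic(cand, t, e)
        best_aic = np.inf
        for r in range(len(cand.columns) + 1):
            for subset in itertools.combinations(cand.columns, r):
                if subset:
                    aic = cox_fit(cand[list(subset)], t, e).aic
                else:
                    aic = stepwise_aic(cand[[]], t, e).fit.aic
                best_aic = min(best_aic, aic)
        assert res.fit.aic <= best_aic + 2.0


class TestRiskScore:
    def test_linear_predictor_properties(self, rng):
        x = pd.DataFrame({"a": rng.integers(0, 2, 60).astype(float), "b": rng.normal(size=60)})
        recs = [generate_survival(0.8 * xi, 0.05, 100.0, rng) for xi in x["a"]]
        t, e = survival_arrays(recs)
        fit = cox_fit(x, t, e)
        s = risk_score(fit, x)
        manual = x.to_numpy() @ fit.summary["coef"].to_numpy()
        np.testing.assert_allclose(s.to_numpy(), manual)
        zero = risk_score(fit, pd.DataFrame({"a": [0.0], "b": [0.0]}))
        assert zero.iloc[0] == 0.0
        with pytest.raises(KeyError):
            risk_score(fit, x[["a"]])


class TestTdROC:
    def test_perfect_score_no_censoring(self, rng):
        t = rng.uniform(1, 50, 200)
        e = np.ones(200, int)
        score = -t  # shorter survival, higher risk: perfect discrimination
        res = time_dependent_auroc(score, t, e, [10.0, 25.0, 40.0])
        np.testing.assert_allclose(res.auroc, 1.0)

    def test_brute_force_pairs_no_censoring(self, rng):
        t = rng.uniform(1, 40, 80)
        e = np.ones(80, int)
        score = rng.normal(size=80)
        horizons = [10.0, 20.0, 30.0]
        res = time_dependent_auroc(score, t, e, horizons)
        for h, got in zip(horizons, res.auroc):
            cases, ctrls = score[t <= h], score[t > h]
            pairs = (cases[:, None] > ctrls[None, :]).mean() + 0.5 * (
                cases[:, None] == ctrls[None, :]
            ).mean()
            assert got == pytest.approx(pairs, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(15, 100) + 0.1
        e = rng.integers(0, 2, 100)
        e[:10] = 1
        score = rng.normal(size=100)
        a = time_dependent_auroc(score, t, e, [8.0]).auroc
        b = time_dependent_auroc(np.exp(2 * score) + 5, t, e, [8.0]).auroc
        np.testing.assert_allclose(a, b)

    def test_matches_scikit_survival_under_censoring(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 150
        score = rng.normal(size=n)
        recs = [generate_survival(0.5 * s, 0.05, 40.0, rng) for s in score]
        t, e = survival_arrays(recs)
        horizons = [5.0, 10.0, 20.0]
        ours = time_dependent_auroc(score, t, e, horizons)
        y = Surv.from_arrays(event=e.astype(bool), time=t)
        ref, _ = cumulative_dynamic_auc(y, y, score, horizons)
        np.testing.assert_allclose(ours.auroc, ref, atol=1e-6)

    def test_no_cases_flagged(self):
        res = time_dependent_auroc([1.0, 2.0], [10.0, 12.0], [1, 1], [5.0])
        assert np.isnan(res.auroc[0])
        assert res.flags
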