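import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fdgquant.regression import (GlucoseSizeModelSpec,
                                 GlucoseSizeRegression, aicc, fit_fixed,
                                 fit_mixed, lrt, model_predict,
                                 select_model, simple_linear_regression,
                                 wald_significance)


def make_data(y, glucose, diameter, mouse=None):
    n = len(y)
    return pd.DataFrame({
        "y": y, "glucose": glucose, "diameter": diameter,
        "mouse_id": mouse if mouse is not None else np.arange(n),
    })


class TestModelPredict:
    def test_inverse_glucose_with_zero_b(self):
        spec = GlucoseSizeModelSpec(3, b_zeroed=True)
        assert model_predict(spec, {"a": 0.27}, 9.0, 5.0) == \
            pytest.approx(0.03)

    def test_model2_reduces_to_model1(self):
        p = {"a": 1.5, "c": 0.0}
        assert model_predict(2, p, 7.0, 4.0) == pytest.approx(1.5)

    def test_model4_reduces_to_model3_b_zeroed(self):
        spec4 = GlucoseSizeModelSpec(4, b_zeroed=True)
        spec3 = GlucoseSizeModelSpec(3, b_zeroed=True)
        val4 = model_predict(spec4, {"a": 0.3, "b": 0.0, "c": 0.0},
                             6.0, 5.0)
        val3 = model_predict(spec3, {"a": 0.3}, 6.0, 5.0)
        assert val4 == pytest.approx(val3)

    def test_division_by_zero_raises(self):
        with pytest.raises(ZeroDivisionError):
            model_predict(GlucoseSizeModelSpec(3), {"a": 1.0, "b": -7.0},
                          7.0, 3.0)

    def test_random_effects_must_exist_in_model(self):
        with pytest.raises(ValueError):
            GlucoseSizeModelSpec(1, random_effects=("c",))


class TestFixedFits:
    def test_exact_constant_data(self):
        data = make_data(np.full(8, 1.8), np.linspace(5, 10, 8),
                         np.linspace(3, 9, 8))
        fit = fit_fixed(GlucoseSizeModelSpec(1), data)
        assert fit.params["a"] == pytest.approx(1.8)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_loglik_closed_form(self, rng):
        y = rng.normal(2.0, 0.3, 12)
        data = make_data(y, rng.uniform(4, 10, 12), rng.uniform(3, 9, 12))
        fit = fit_fixed(GlucoseSizeModelSpec(1), data)
        n, rss = fit.n, fit.rss
        expected = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
        assert fit.loglik == pytest.approx(expected, rel=1e-12)

    def test_inverse_glucose_estimator_unbiased(self):
        """Monte-Carlo mean of the slope-through-origin estimator over
        200 replicates lands within 2 SE of the truth."""
        a_true, ests = 0.27, []
        for rep in range(200):
            r = np.random.default_rng(rep)
            g = np.clip(r.normal(8.1, 2.4, 22), 3.0, None)
            y = a_true / g + r.normal(0.0, 0.0144, 22)
            data = make_data(y, g, np.full(22, 5.0))
            fit = fit_fixed(GlucoseSizeModelSpec(3, b_zeroed=True), data)
            ests.append(fit.params["a"])
        se = np.std(ests) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - a_true) < 3.2 * se

    def test_free_b_recovered_noiseless(self):
        g = np.linspace(4.0, 12.0, 15)
        y = 0.5 / (2.0 + g)
        data = make_data(y, g, np.full(15, 5.0))
        fit = fit_fixed(GlucoseSizeModelSpec(3), data)
        assert fit.params["b"] == pytest.approx(2.0, abs=1e-4)
        assert fit.params["a"] == pytest.approx(0.5, rel=1e-4)

    def test_nesting_rss_inequality(self, rng):
        y = rng.normal(1.0, 0.2, 20) + 0.05 * rng.uniform(3, 9, 20)
        data = make_data(y, rng.uniform(4, 10, 20), rng.uniform(3, 9, 20))
        rss1 = fit_fixed(GlucoseSizeModelSpec(1), data).rss
        rss2 = fit_fixed(GlucoseSizeModelSpec(2), data).rss
        rss3 = fit_fixed(GlucoseSizeModelSpec(3), data).rss
        rss4 = fit_fixed(GlucoseSizeModelSpec(4), data).rss
        assert rss2 <= rss1 + 1e-12
        assert rss4 <= rss3 + 1e-9


class TestMixedFits:
    @staticmethod
    def grouped_data(seed, n_mice=8, per=2, a=0.04, tau=0.014,
                     sigma=0.003):
        r = np.random.default_rng(seed)
        mouse = np.repeat(np.arange(n_mice), per)
        eta = r.normal(0.0, tau, n_mice)
        n = n_mice * per
        y = a + eta[mouse] + r.normal(0.0, sigma, n)
        return make_data(y, r.uniform(4, 10, n), r.uniform(3, 9, n),
                         mouse)

    def test_matches_statsmodels_single_random_effect(self):
        import statsmodels.api as sm
        data = self.grouped_data(3, n_mice=9, per=3, a=1.0, tau=0.3,
                                 sigma=0.2)
        fit = fit_mixed(GlucoseSizeModelSpec(1), data, ("a",))
        md = sm.MixedLM(data["y"].to_numpy(),
                        np.ones((len(data), 1)),
                        groups=data["mouse_id"].to_numpy())
        ref = md.fit(reml=False)
        assert fit.params["a"] == pytest.approx(ref.fe_params[0],
                                                rel=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert fit.random_sd["a"] == pytest.approx(
            math.sqrt(float(np.asarray(ref.cov_re)[0, 0])), rel=1e-3)

    def test_matches_statsmodels_two_random_effects_diagonal(self):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLMParams
        r = np.random.default_rng(12)
        mouse = np.repeat(np.arange(12), 4)
        d = r.uniform(3, 9, 48)
        y = (1.0 + r.normal(0, 0.5, 12)[mouse]
             + (0.3 + r.normal(0, 0.08, 12)[mouse]) * d
             + r.normal(0, 0.1, 48))
        data = make_data(y, r.uniform(4, 10, 48), d, mouse)
        fit = fit_mixed(GlucoseSizeModelSpec(2), data, ("a", "c"))
        exog = np.column_stack([np.ones(48), d])
        md = sm.MixedLM(y, exog, groups=mouse, exog_re=exog)
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2))
        ref = md.fit(reml=False, free=free, method="lbfgs", maxiter=2000)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert fit.params["a"] == pytest.approx(ref.fe_params[0],
                                                rel=1e-3)
        assert fit.params["c"] == pytest.approx(ref.fe_params[1],
                                                rel=1e-3)
        assert fit.random_sd["a"] == pytest.approx(
            math.sqrt(float(np.asarray(ref.cov_re)[0, 0])), rel=1e-2)

    def test_degenerate_between_variance_collapses_to_fixed(self):
        """With no true between-mouse variance the random SD estimate is
        negligible and the mixed log-likelihood essentially matches the
        fixed fit (the degenerate pattern seen when repeated measures
        add nothing)."""
        data = self.grouped_data(7, tau=0.0)
        fx = fit_fixed(GlucoseSizeModelSpec(1), data)
        mx = fit_mixed(GlucoseSizeModelSpec(1), data, ("a",))
        assert mx.random_sd["a"] < mx.sigma
        assert mx.loglik == pytest.approx(fx.loglik, abs=0.5)
        assert mx.loglik >= fx.loglik - 1e-6

    def test_variance_components_recovered(self):
        """Between/within SDs of an intercept-only mixed model over 200
        replicates of 8 mice x 2 sessions recover truth within 30%."""
        taus, sigmas = [], []
        for rep in range(200):
            data = self.grouped_data(1000 + rep)
            mx = fit_mixed(GlucoseSizeModelSpec(1), data, ("a",))
            taus.append(mx.random_sd["a"])
            sigmas.append(mx.sigma)
        assert abs(np.mean(taus) - 0.014) / 0.014 < 0.30
        assert abs(np.mean(sigmas) - 0.003) / 0.003 < 0.30

    def test_row_permutation_invariance(self):
        data = self.grouped_data(11, tau=0.02)
        perm = data.sample(frac=1.0, random_state=4).reset_index(
            drop=True)
        f1 = fit_mixed(GlucoseSizeModelSpec(1), data, ("a",))
        f2 = fit_mixed(GlucoseSizeModelSpec(1), perm, ("a",))
        assert f1.params["a"] == pytest.approx(f2.params["a"], rel=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_mixed_never_below_fixed_loglik(self):
        for seed in range(6):
            data = self.grouped_data(seed, tau=0.01)
            fx = fit_fixed(GlucoseSizeModelSpec(1), data)
            mx = fit_mixed(GlucoseSizeModelSpec(1), data, ("a",))
            assert mx.loglik >= fx.loglik - 1e-4


class TestInformationCriteria:
    def test_lrt_matches_published_chi_square_tails(self):
        D, p = lrt(0.0, 7.16 / 2.0, df=1)
        assert D == pytest.approx(7.16)
        assert p == pytest.approx(0.0075, abs=5e-5)
        D, p = lrt(0.0, 3.95 / 2.0, df=1)
        assert p == pytest.approx(0.047, abs=5e-4)

    def test_equal_logliks_give_unit_p(self):
        D, p = lrt(-10.0, -10.0, df=1)
        assert D == 0.0 and p == 1.0

    def test_negative_d_beyond_tolerance_raises(self):
        with pytest.raises(ValueError):
            lrt(0.0, -5.0, df=1)

    def test_aicc_value(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4.0 + 12.0 / 7.0)

    def test_aicc_tends_to_aic(self):
        assert aicc(-50.0, 3, 10 ** 7) == pytest.approx(106.0, abs=1e-4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(20, 200))
    def test_aicc_penalty_monotone_in_k(self, k, n):
        assert aicc(-10.0, k + 1, n) > aicc(-10.0, k, n)

    def test_aicc_requires_enough_data(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestWald:
    def test_large_ratio_significant(self):
        fit = fit_fixed(GlucoseSizeModelSpec(1),
                        make_data(np.r_[np.full(5, 1.0), np.full(5, 1.1)],
                                  np.linspace(4, 10, 10),
                                  np.linspace(3, 9, 10)))
        fit.params["x"], fit.se["x"] = 10.0, 1.0
        assert wald_significance(fit, "x")
        fit.params["x"], fit.se["x"] = 0.1, 5.0
        assert not wald_significance(fit, "x")

    def test_null_b_rarely_flagged(self):
        """With data generated at b = 0, the Wald test keeps its size:
        b flagged non-significant in >= 90% of 200 replicates."""
        kept = 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            g = np.clip(r.normal(8.0, 2.0, 22), 3.0, None)
            y = 0.27 / g + r.normal(0.0, 0.015, 22)
            data = make_data(y, g, np.full(22, 5.0))
            fit = fit_fixed(GlucoseSizeModelSpec(3), data)
            try:
                sig = wald_significance(fit, "b")
            except ValueError:
                sig = False
            kept += not sig
        assert kept >= 180


class TestSelection:
    def test_inverse_glucose_truth_selects_model3_fixed(self):
        """Data from Y = a/[Glc] with no grouping variance: model 3
        (b = 0, fixed effects) chosen in >= 80% of 100 replicates."""
        wins = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            g = np.clip(r.normal(8.1, 2.4, 22), 3.0, None)
            d = r.uniform(3, 9, 22)
            y = 0.27 / g + r.normal(0.0, 0.0144, 22)
            data = make_data(y, g, d, np.repeat(np.arange(11), 2))
            rep_out = select_model(data)
            wins += (rep_out.chosen_model == 3
                     and rep_out.chosen_fit.method == "fixed")
        assert wins >= 80

    def test_strong_grouping_truth_adopts_mixed_model1(self):
        """Data from Y = a with large between-mouse SD: the mixed
        intercept-only model is adopted in >= 80% of replicates."""
        wins = 0
        for rep in range(50):
            data = TestMixedFits.grouped_data(500 + rep, n_mice=8, per=2,
                                              a=0.04, tau=0.02,
                                              sigma=0.003)
            rep_out = select_model(data)
            chosen = rep_out.representatives[rep_out.chosen_model]
            wins += (rep_out.chosen_model == 1
                     and chosen.method == "mixed")
        assert wins >= 40

    def test_single_mouse_skips_mixed(self):
        r = np.random.default_rng(0)
        data = make_data(r.normal(1.0, 0.1, 10), r.uniform(4, 10, 10),
                         r.uniform(3, 9, 10), np.zeros(10, dtype=int))
        rep = select_model(data)
        assert all(f.method == "fixed"
                   for f in rep.representatives.values())

    def test_report_table_has_one_chosen_model(self):
        data = TestMixedFits.grouped_data(1)
        rep = select_model(data)
        table = rep.table()
        assert table["chosen"].sum() == 1
        assert rep.ranking[0] == rep.chosen_model


class TestEstimatorAPI:
    def test_get_set_params_round_trip(self):
        est = GlucoseSizeRegression(model_id=3, b_zeroed=True)
        est2 = GlucoseSizeRegression(**est.get_params())
        assert est2.get_params() == est.get_params()
        est2.set_params(model_id=2)
        assert est2.model_id == 2
        with pytest.raises(ValueError):
            est2.set_params(bogus=1)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        est = GlucoseSizeRegression(model_id=4, random_effects=("a",))
        cl = clone(est)
        assert cl.get_params() == est.get_params()

    def test_predict_matches_model_formula(self, rng):
        g = rng.uniform(4, 10, 15)
        y = 0.3 / g + rng.normal(0, 0.001, 15)
        est = GlucoseSizeRegression(3, b_zeroed=True)
        X = np.column_stack([g, np.full(15, 5.0)])
        est.fit(X, y)
        pred = est.predict(X)
        assert np.allclose(pred, est.params_["a"] / g)

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            GlucoseSizeRegression().predict(np.ones((3, 2)))


class TestSimpleLinearRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        slope, icpt, r2, p = simple_linear_regression(2.0 * x + 1.0, x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_known_five_points(self):
        # hand-computed OLS: x=[1..5], y=[2,1,4,3,5]
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        slope, icpt, r2, p = simple_linear_regression(y, x)
        assert slope == pytest.approx(0.8)   # Sxy/Sxx = 8/10
        assert icpt == pytest.approx(0.6)    # ybar - slope*xbar
        assert r2 == pytest.approx(0.64, abs=1e-9)

    def test_null_calibration(self):
        """With y independent of x the slope p-value is uniform: ~5%
        rejections at alpha = 0.05 over 1000 replicates."""
        rejections = 0
        for rep in range(1000):
            r = np.random.default_rng(rep)
            _, _, _, p = simple_linear_regression(r.normal(size=100),
                                                  r.normal(size=100))
            rejections += p < 0.05
        assert 30 <= rejections <= 75

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            simple_linear_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            simple_linear_regression([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
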