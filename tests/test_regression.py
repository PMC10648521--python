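import numpy as np
import pytest

from bctdensity.phantom import CohortSimSpec, simulate_cohort
from bctdensity.reference import PUBLISHED_MODELS, age_group_table
from bctdensity.regression import (
    fit_age_model,
    predict,
    residual_standard_error,
    rse_from_group_stats,
)

from oracles import wls_normal_equations


class TestFitAgeModel:
    def test_noiseless_recovery(self):
        ages = np.arange(40, 75)
        y = 2.0 * np.log(ages) + 1.0
        fit = fit_age_model(ages, y, "log")
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.b == pytest.approx(1.0, abs=1e-9)
        assert fit.rse == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        ages = np.array([41.0, 48.0, 55.0, 63.0, 70.0])
        y = np.array([500.0, 520.0, 610.0, 650.0, 640.0])
        fit = fit_age_model(ages, y, "log")
        a, b = wls_normal_equations(np.log(ages), y)
        assert fit.a == pytest.approx(a, abs=1e-10)
        assert fit.b == pytest.approx(b, abs=1e-10)

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        tab = age_group_table()
        fit = fit_age_model(tab["age_mean"], tab["btv_mean"], "log", weights=tab["n"])
        X = sm.add_constant(np.log(tab["age_mean"].to_numpy()))
        res = sm.WLS(tab["btv_mean"].to_numpy(), X, weights=tab["n"].to_numpy()).fit()
        assert fit.a == pytest.approx(res.params[1], abs=1e-8)
        assert fit.b == pytest.approx(res.params[0], abs=1e-8)

    def test_group_mean_fit_near_published_models(self):
        """Count-weighted fits on the reference age-group means land within
        10% of the published coefficients."""
        tab = age_group_table()
        fit_btv = fit_age_model(tab["age_mean"], tab["btv_mean"], "log", weights=tab["n"])
        assert fit_btv.a == pytest.approx(PUBLISHED_MODELS["btv"]["a"], rel=0.10)
        assert fit_btv.b == pytest.approx(PUBLISHED_MODELS["btv"]["b"], rel=0.10)
        fit_mgv = fit_age_model(
            tab["age_mean"], tab["mgv_mean"], "inverse", weights=tab["n"]
        )
        assert fit_mgv.a == pytest.approx(PUBLISHED_MODELS["mgv"]["a"], rel=0.10)

    def test_weighted_fit_equals_row_replication(self):
        ages = np.array([42.0, 52.0, 62.0, 72.0])
        y = np.array([100.0, 90.0, 70.0, 65.0])
        w = np.array([3, 1, 4, 2])
        fit_w = fit_age_model(ages, y, "inverse", weights=w)
        fit_r = fit_age_model(np.repeat(ages, w), np.repeat(y, w), "inverse")
        assert fit_w.a == pytest.approx(fit_r.a, abs=1e-10)
        assert fit_w.b == pytest.approx(fit_r.b, abs=1e-10)
        assert fit_w.se_a == pytest.approx(fit_r.se_a, abs=1e-10)
        assert fit_w.se_b == pytest.approx(fit_r.se_b, abs=1e-10)
        assert fit_w.df == fit_r.df

    def test_degenerate_design_fails(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_age_model([50, 50, 50], [1.0, 2.0, 3.0], "log")

    def test_nonpositive_age_fails(self):
        with pytest.raises(ValueError, match="positive"):
            fit_age_model([-1, 50, 60], [1.0, 2.0, 3.0], "log")


class TestRSE:
    def test_perfect_fit_zero(self):
        ages = np.arange(40, 50)
        y = 3.0 / ages + 0.5
        fit = fit_age_model(ages, y, "inverse")
        assert residual_standard_error(fit, ages, y) == pytest.approx(0.0, abs=1e-10)

    def test_hand_arithmetic_residuals(self):
        """Residuals (1, -1, 1, -1) with n=4 give sqrt(4/2) = 1.4142."""
        ages = np.array([41.0, 47.0, 61.0, 70.0])
        fit = fit_age_model(ages, 2.0 * np.log(ages) + 1.0, "log")
        y = fit.predict(ages) + np.array([1.0, -1.0, 1.0, -1.0])
        assert residual_standard_error(fit, ages, y) == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_rse_is_scaled_rms_residual(self):
        rng = np.random.default_rng(1)
        ages = rng.integers(40, 75, 60).astype(float)
        y = 100.0 / ages + rng.normal(0, 3, 60)
        fit = fit_age_model(ages, y, "inverse")
        resid = y - fit.predict(ages)
        rms = np.sqrt(np.mean(resid**2))
        n = ages.size
        assert residual_standard_error(fit, ages, y) == pytest.approx(
            rms * np.sqrt(n / (n - 2)), abs=1e-10
        )

    def test_single_group_on_curve_zero(self):
        tab = age_group_table()
        fit = fit_age_model(tab["age_mean"], tab["btv_mean"], "log", weights=tab["n"])
        yhat = float(fit.predict(57.0)[0])
        assert rse_from_group_stats([100], [57.0], [yhat], [0.0], fit) == pytest.approx(0.0)

    def test_grouped_formula_matches_raw_sse(self):
        """With group-constant ages, the grouped SSE identity is exact."""
        rng = np.random.default_rng(2)
        group_ages = np.array([42.0, 52.0, 62.0, 72.0])
        ns = np.array([30, 50, 40, 20])
        ages = np.repeat(group_ages, ns)
        y = 5000.0 / ages - 20.0 + rng.normal(0, 30, ages.size)
        fit = fit_age_model(ages, y, "inverse")
        rse_raw = residual_standard_error(fit, ages, y)
        means = [y[ages == a].mean() for a in group_ages]
        sds = [y[ages == a].std(ddof=1) for a in group_ages]
        rse_grouped = rse_from_group_stats(ns, group_ages, means, sds, fit)
        assert rse_grouped == pytest.approx(rse_raw, rel=1e-6)

    def test_published_rse_reconstruction(self):
        tab = age_group_table()
        for feature, family in (("btv", "log"), ("mgv", "inverse"), ("pbd", "inverse")):
            fit = fit_age_model(
                tab["age_mean"], tab[f"{feature}_mean"], family, weights=tab["n"]
            )
            rse = rse_from_group_stats(
                tab["n"], tab["age_mean"], tab[f"{feature}_mean"],
                tab[f"{feature}_sd"], fit,
            )
            assert rse == pytest.approx(PUBLISHED_MODELS[feature]["rse"], rel=0.02)


class TestPredict:
    def test_published_curve_values(self):
        """Arithmetic on the published coefficients: MGV at 72 and PBD at 42."""
        from bctdensity.regression import RegressionFit

        mgv = RegressionFit("inverse", 4885.0, -26.0, 0, 0, 1, 1, 0, 1, 3)
        assert predict(mgv, 72)[0] == pytest.approx(4885 / 72 - 26, abs=1e-9)
        assert predict(mgv, 72)[0] == pytest.approx(41.85, abs=0.01)
        pbd = RegressionFit("inverse", 1237.0, -8.4, 0, 0, 1, 1, 0, 1, 3)
        assert predict(pbd, 42)[0] == pytest.approx(1237 / 42 - 8.4, abs=1e-9)
        assert predict(pbd, 42)[0] == pytest.approx(21.05, abs=0.01)

    def test_inverse_family_decreases_with_age(self):
        tab = age_group_table()
        fit = fit_age_model(tab["age_mean"], tab["mgv_mean"], "inverse", weights=tab["n"])
        assert fit.a > 0
        curve = fit.predict(np.arange(40, 75))
        assert (np.diff(curve) < 0).all()

    def test_nonpositive_age_fails(self):
        fit = fit_age_model([42.0, 57.0, 72.0], [1.0, 2.0, 3.0], "log")
        with pytest.raises(ValueError, match="positive"):
            fit.predict([0.0])


class TestParameterRecovery:
    def test_simulated_cohorts_recover_generating_coefficients(self):
        """200 cohorts of n=1033 with the published RSEs as noise: the mean
        fitted slope stays within 3 simulation SEs of the generating slope."""
        tab = age_group_table()
        bin_counts = tuple(tab["n"])
        estimates = {"btv": [], "mgv": [], "pbd": []}
        for rep in range(200):
            cohort = simulate_cohort(CohortSimSpec(bin_counts=bin_counts, seed=1000 + rep))
            for feature, family in (("btv", "log"), ("mgv", "inverse"), ("pbd", "inverse")):
                fit = fit_age_model(cohort["age"], cohort[feature], family)
                estimates[feature].append(fit.a)
        for feature in estimates:
            a_true = PUBLISHED_MODELS[feature]["a"]
            a_hat = np.asarray(estimates[feature])
            assert abs(a_hat.mean() - a_true) <= 3.0 * a_hat.std(ddof=1), feature
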