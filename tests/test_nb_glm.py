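"""NB-GLM engine: likelihood, deviance, diagnostics and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from tickburden.errors import SchemaError, SingularityError, ValidationError
from tickburden.nb_glm import (
    fit_nb,
    nb_deviance,
    nb_loglik,
    overdispersion_check,
    predict_burden,
    significance_stars,
    stepwise_aic,
    vif,
)

from conftest import nb_frame


class TestFitNB:
    def test_intercept_only_fits_sample_mean_exactly(self):
        frame = pd.DataFrame({"tick_count": [3, 3, 3, 3]})
        fit = fit_nb(frame, [])
        assert np.allclose(fit.fitted, 3.0)
        assert fit.explained_deviance == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_mean_on_heterogeneous_counts(self):
        frame = pd.DataFrame({"tick_count": [0, 1, 2, 8, 4, 0, 3]})
        fit = fit_nb(frame, [])
        assert np.allclose(fit.fitted, np.mean(frame["tick_count"]), rtol=1e-6)

    def test_parameter_recovery_against_direct_ml(self):
        # simulate log mu = 1.0 + 0.5 x, theta = 1; cross-check the alternating
        # fitter against a generic joint optimiser of the same likelihood
        rng = np.random.default_rng(123)
        frame = nb_frame(rng, 10_000, 1.0, 0.5, 1.0)
        fit = fit_nb(frame, ["x"])
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=0.05)
        assert fit.params["x"] == pytest.approx(0.5, abs=0.05)
        assert fit.theta == pytest.approx(1.0, abs=0.1)

        y = frame["tick_count"].to_numpy()
        X = np.column_stack([np.ones(len(frame)), frame["x"]])

        def negll(par):
            return -nb_loglik(y, np.exp(X @ par[:2]), np.exp(par[2]))

        res = optimize.minimize(negll, x0=[0.0, 0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)
        assert fit.params["x"] == pytest.approx(res.x[1], abs=1e-3)

    def test_loglik_matches_scipy_pmf(self):
        rng = np.random.default_rng(5)
        frame = nb_frame(rng, 500, 0.8, 0.3, 2.0)
        fit = fit_nb(frame, ["x"])
        direct = stats.nbinom.logpmf(
            frame["tick_count"], fit.theta, fit.theta / (fit.theta + fit.fitted)
        ).sum()
        assert fit.loglik == pytest.approx(direct, abs=1e-8)

    def test_all_zero_response_degenerate_status(self):
        frame = pd.DataFrame({"tick_count": [0] * 20, "x": np.arange(20.0)})
        fit = fit_nb(frame, ["x"])
        assert fit.status == "degenerate_all_zero"
        assert not fit.converged

    def test_negative_or_noninteger_response_rejected(self):
        with pytest.raises(ValidationError):
            fit_nb(pd.DataFrame({"tick_count": [1, -2, 3, 4, 5]}), [])
        with pytest.raises(ValidationError):
            fit_nb(pd.DataFrame({"tick_count": [1.5, 2.0, 3.0, 4.0, 5.0]}), [])

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(0)
        frame = nb_frame(rng, 100, 1.0, 0.3, 1.0)
        frame["x2"] = 2.0 * frame["x"]
        with pytest.raises(SingularityError):
            fit_nb(frame, ["x", "x2"])

    def test_poisson_limit_matches_poisson_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.normal(size=5000)
        mu = np.exp(1.0 + 0.4 * x)
        frame = pd.DataFrame({"tick_count": rng.poisson(mu), "x": x})
        fit = fit_nb(frame, ["x"])
        X = np.column_stack([np.ones(len(x)), x])
        pois = sm.GLM(frame["tick_count"], X, family=sm.families.Poisson()).fit()
        assert fit.params["Intercept"] == pytest.approx(pois.params[0], abs=1e-3)
        assert fit.params["x"] == pytest.approx(pois.params[1], abs=1e-3)

    def test_deviance_zero_count_convention(self):
        # y log(y/mu) must contribute 0 at y = 0
        assert nb_deviance(np.array([0.0]), np.array([1e-9]), 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_adding_predictor_never_increases_deviance_at_fixed_theta(self):
        rng = np.random.default_rng(21)
        frame = nb_frame(rng, 800, 1.0, 0.4, 1.0)
        frame["noise"] = rng.normal(size=len(frame))
        base = fit_nb(frame, ["x"], theta=1.0)
        bigger = fit_nb(frame, ["x", "noise"], theta=1.0)
        assert bigger.deviance <= base.deviance + 1e-6

    def test_null_deviance_bounds_residual(self):
        rng = np.random.default_rng(3)
        frame = nb_frame(rng, 600, 1.2, 0.5, 0.8)
        fit = fit_nb(frame, ["x"])
        assert fit.deviance >= 0
        assert fit.null_deviance >= fit.deviance - 1e-6
        assert -1e-9 <= fit.explained_deviance <= 1.0


class TestPredict:
    def test_training_data_reproduces_fitted_means(self):
        rng = np.random.default_rng(11)
        frame = nb_frame(rng, 400, 1.0, 0.5, 1.0)
        fit = fit_nb(frame, ["x"])
        assert np.allclose(predict_burden(fit, frame), fit.fitted, rtol=1e-8)

    def test_zero_covariates_give_exp_intercept(self):
        rng = np.random.default_rng(12)
        frame = nb_frame(rng, 400, 1.0, 0.5, 1.0)
        fit = fit_nb(frame, ["x"])
        pred = predict_burden(fit, pd.DataFrame({"x": [0.0]}))
        assert pred[0] == pytest.approx(np.exp(fit.params["Intercept"]))

    def test_log_link_multiplicative_identity(self):
        rng = np.random.default_rng(13)
        frame = nb_frame(rng, 400, 1.0, 0.5, 1.0)
        fit = fit_nb(frame, ["x"])
        p1 = predict_burden(fit, pd.DataFrame({"x": [1.0]}))[0]
        p2 = predict_burden(fit, pd.DataFrame({"x": [2.0]}))[0]
        assert p2 / p1 == pytest.approx(np.exp(fit.params["x"]))

    def test_missing_column_is_schema_error(self):
        rng = np.random.default_rng(14)
        frame = nb_frame(rng, 100, 1.0, 0.5, 1.0)
        fit = fit_nb(frame, ["x"])
        with pytest.raises(SchemaError, match="x"):
            predict_burden(fit, pd.DataFrame({"z": [1.0]}))


class TestOverdispersion:
    def test_poisson_data_near_one(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=10_000)
        frame = pd.DataFrame({"tick_count": rng.poisson(np.exp(1.0 + 0.3 * x)), "x": x})
        assert overdispersion_check(frame, ["x"]) == pytest.approx(1.0, abs=0.1)

    def test_nb_data_matches_closed_form(self):
        # Pearson dispersion of NB data approx 1 + mu/theta = 1 + 5/0.5 = 11
        rng = np.random.default_rng(32)
        theta, mu = 0.5, 5.0
        y = rng.negative_binomial(theta, theta / (theta + mu), 10_000)
        frame = pd.DataFrame({"tick_count": y})
        assert overdispersion_check(frame, []) == pytest.approx(11.0, rel=0.2)

    def test_constant_response_zero(self):
        frame = pd.DataFrame({"tick_count": [4] * 50})
        assert overdispersion_check(frame, []) == pytest.approx(0.0, abs=1e-12)


class TestVIF:
    def test_orthogonal_predictors_give_one(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        frame = pd.DataFrame({"a": x1, "b": x2})
        v = vif(frame, ["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=1e-10)
        assert v["b"] == pytest.approx(1.0, abs=1e-10)

    def test_correlated_pair_closed_form(self):
        # two predictors with exact sample correlation r -> VIF = 1/(1-r^2)
        n, r = 1000, 0.6
        rng = np.random.default_rng(41)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        # orthonormalise, then mix to achieve exact correlation
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        mixed = r * a + np.sqrt(1 - r**2) * b
        frame = pd.DataFrame({"a": a, "b": mixed})
        v = vif(frame, ["a", "b"])
        assert v["a"] == pytest.approx(1.5625, abs=1e-9)
        assert v["b"] == pytest.approx(1.5625, abs=1e-9)

    def test_exact_collinearity_flagged_infinite(self):
        rng = np.random.default_rng(42)
        frame = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        frame["c"] = frame["a"] + frame["b"]
        v = vif(frame, ["a", "b", "c"])
        assert np.isinf(v["c"])

    def test_constant_predictor_rejected_by_name(self):
        frame = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(ValidationError, match="'b'"):
            vif(frame, ["a", "b"])


class TestStepwise:
    def test_empty_candidates_returns_intercept_only(self):
        rng = np.random.default_rng(51)
        frame = nb_frame(rng, 200, 1.0, 0.0, 1.0)
        res = stepwise_aic(frame, [])
        assert res.fit.predictors == []
        assert [t for t in res.trace if t[0] != "start"] == []

    def test_single_true_predictor_among_noise_selected(self):
        rng = np.random.default_rng(52)
        frame = nb_frame(rng, 2000, 1.0, 0.5, 1.0)
        for j in range(5):
            frame[f"n{j}"] = rng.normal(size=len(frame))
        res = stepwise_aic(frame, ["x"] + [f"n{j}" for j in range(5)])
        assert "x" in res.fit.predictors

    def test_selected_aic_never_above_null(self):
        rng = np.random.default_rng(53)
        frame = nb_frame(rng, 500, 1.0, 0.4, 1.0)
        frame["n0"] = rng.normal(size=len(frame))
        res = stepwise_aic(frame, ["x", "n0"])
        null_aic = fit_nb(frame, []).aic
        assert res.fit.aic <= null_aic + 1e-9

    def test_trace_records_moves(self):
        rng = np.random.default_rng(54)
        frame = nb_frame(rng, 1000, 1.0, 0.6, 1.0)
        res = stepwise_aic(frame, ["x"])
        actions = [a for a, _, _ in res.trace]
        assert actions[0] == "start"
        assert "add" in actions


def test_significance_star_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.07) == "#"
    assert significance_stars(0.5) == "ns"
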