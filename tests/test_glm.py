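"""Logistic-fit contracts: closed-form 2x2 oracles, independent optimizer and
statsmodels cross-checks, separation handling, and prediction invariances."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from bipolar_rf.errors import (
    DegenerateOutcomeError,
    InvalidInputError,
    SchemaError,
    SeparationWarning,
)
from bipolar_rf.glm import (
    FitOptions,
    FittedModel,
    ModelSpec,
    fit_logistic,
    linear_predictor,
    predict_probability,
)

from conftest import two_by_two


def _manual_model(outcome, predictors, intercept, coefs):
    return FittedModel(
        spec=ModelSpec(outcome, tuple(predictors)),
        intercept=intercept,
        coefficients=dict(zip(predictors, coefs)),
        standard_errors={p: 0.0 for p in predictors},
        intercept_se=0.0,
        converged=True,
        n_used=0,
        log_likelihood=0.0,
    )


class TestTwoByTwoOracles:
    def test_balanced_table_gives_null_fit(self):
        fit = fit_logistic(two_by_two(25, 25, 25, 25), ModelSpec("y", ("x",)))
        assert fit.intercept == pytest.approx(0.0, abs=1e-7)
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-7)

    def test_slope_equals_log_odds_ratio(self):
        # cells a=8, b=2, c=4, d=6: slope = ln(8*6 / (2*4)), intercept = ln(c/d)
        fit = fit_logistic(two_by_two(8, 2, 4, 6), ModelSpec("y", ("x",)))
        assert fit.coefficients["x"] == pytest.approx(math.log(48 / 8), abs=1e-6)
        assert fit.intercept == pytest.approx(math.log(4 / 6), abs=1e-6)
        assert fit.converged and fit.log_likelihood < 0


class TestAgainstIndependentMaximizers:
    def test_irls_matches_direct_likelihood_maximizer(self, dev_cohort):
        spec = ModelSpec("steam_pop", ("rf_power", "pct_imp_drop5", "thickness"))
        fit = fit_logistic(dev_cohort, spec)
        X = np.column_stack(
            [np.ones(len(dev_cohort))]
            + [dev_cohort[p].to_numpy() for p in spec.predictors]
        )
        y = dev_cohort["steam_pop"].to_numpy(float)

        def nll(beta):
            eta = X @ beta
            return -(y @ eta - np.logaddexp(0, eta).sum())

        def grad(beta):
            mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
            return X.T @ (mu - y)

        res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 1000})
        np.testing.assert_allclose(fit.coef_vector(), res.x, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-8)

    def test_matches_statsmodels(self, dev_cohort):
        sm = pytest.importorskip("statsmodels.api")
        spec = ModelSpec("transmural", ("rf_power", "rf_duration", "thickness"))
        fit = fit_logistic(dev_cohort, spec)
        X = sm.add_constant(dev_cohort[list(spec.predictors)])
        ref = sm.GLM(dev_cohort["transmural"], X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef_vector(), ref.params.to_numpy(),
                                   rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(
            [fit.intercept_se] + [fit.standard_errors[p] for p in spec.predictors],
            ref.bse.to_numpy(), rtol=1e-4,
        )


class TestPrediction:
    def test_null_model_predicts_half(self):
        model = _manual_model("steam_pop", ["thickness"], 0.0, [0.0])
        rows = pd.DataFrame({"thickness": [1.0, 10.0, 25.0]})
        np.testing.assert_allclose(predict_probability(model, rows), 0.5)

    def test_printed_boundary_equation_worked_example(self):
        # logit = -4.9498 + 1.0729*t - 0.09030*E at t=10 mm, E=30 W
        model = _manual_model("steam_pop", ["thickness", "rf_power"],
                              -4.9498, [1.0729, -0.09030])
        row = pd.DataFrame({"thickness": [10.0], "rf_power": [30.0]})
        eta = linear_predictor(model, row)
        assert eta[0] == pytest.approx(3.0702, abs=1e-10)
        assert predict_probability(model, row)[0] == pytest.approx(0.9556, abs=5e-5)

    def test_missing_column_raises_schema_error(self):
        model = _manual_model("steam_pop", ["thickness"], 0.0, [1.0])
        with pytest.raises(SchemaError):
            predict_probability(model, pd.DataFrame({"rf_power": [30.0]}))

    def test_affine_rescaling_leaves_probabilities_unchanged(self, dev_cohort):
        spec = ModelSpec("transmural", ("rf_power", "thickness"))
        base = fit_logistic(dev_cohort, spec)
        scaled = dev_cohort.copy()
        scaled["thickness"] = 2.5 * scaled["thickness"] + 7.0
        refit = fit_logistic(scaled, spec)
        np.testing.assert_allclose(
            predict_probability(base, dev_cohort),
            predict_probability(refit, scaled),
            atol=1e-6,
        )
        assert refit.coefficients["thickness"] == pytest.approx(
            base.coefficients["thickness"] / 2.5, rel=1e-4
        )


class TestDegenerateInputs:
    def test_single_class_outcome_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1, 1, 1]})
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(df, ModelSpec("y", ("x",)))

    def test_empty_predictors_rejected(self):
        with pytest.raises(InvalidInputError):
            ModelSpec("y", ())

    def test_duplicate_predictors_rejected(self):
        with pytest.raises(InvalidInputError):
            ModelSpec("y", ("x", "x"))

    def test_separation_warns_and_flags(self):
        # x perfectly separates y
        df = pd.DataFrame({"x": np.arange(20.0), "y": [0] * 10 + [1] * 10})
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(df, ModelSpec("y", ("x",)))
        assert fit.separation_flag and not fit.converged

    def test_ridge_option_tames_separation(self):
        df = pd.DataFrame({"x": np.arange(20.0), "y": [0] * 10 + [1] * 10})
        fit = fit_logistic(df, ModelSpec("y", ("x",)), FitOptions(ridge=1e-2))
        assert np.isfinite(fit.coefficients["x"])
        assert fit.ridge_used == 1e-2


def test_fitted_model_json_round_trip(dev_cohort):
    spec = ModelSpec("steam_pop", ("rf_power", "thickness"))
    fit = fit_logistic(dev_cohort, spec)
    back = FittedModel.from_json(fit.to_json())
    assert back.spec == fit.spec
    assert back.coefficients == fit.coefficients
    assert back.log_likelihood == fit.log_likelihood
    assert back.converged == fit.converged
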