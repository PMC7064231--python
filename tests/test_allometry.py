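import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mangrove_allometry.allometry import (
    AllometricModel,
    ModelForm,
    ModelFormName,
    aic,
    compute_fit_metrics,
    fit_model,
    mpe,
    predict,
    r2_adjusted,
    residual_diagnostics,
    rmse,
    select_best,
)

POWER = ModelForm(ModelFormName.POWER, ("x",))
QUAD = ModelForm(ModelFormName.QUADRATIC, ("x",))
LIN2 = ModelForm(ModelFormName.LINEAR_MULTI, ("h", "rho"))
PMULTI = ModelForm(ModelFormName.POWER_MULTI, ("D", "h"))


class TestPredict:
    def test_power_at_unit_predictor_returns_scale(self):
        m = AllometricModel(POWER, (0.07577, 1.98745))
        assert predict(m, {"x": 1.0}) == pytest.approx(0.07577)
        m2 = AllometricModel(POWER, (0.465, 1.024))
        assert predict(m2, {"x": 1.0}) == pytest.approx(0.465)

    def test_quadratic_sums_coefficients_at_one(self):
        m = AllometricModel(QUAD, (0.0236337, -0.0052021, 0.0001993))
        assert predict(m, {"x": 1.0}) == pytest.approx(0.0186309)

    def test_missing_predictor_named(self):
        m = AllometricModel(LIN2, (1.0, 2.0, 3.0))
        with pytest.raises(KeyError, match="rho"):
            predict(m, {"h": 100.0})

    def test_negative_base_under_fractional_exponent_rejected(self):
        m = AllometricModel(POWER, (0.5, 1.5))
        with pytest.raises(ValueError, match="fractional"):
            predict(m, {"x": -2.0})

    def test_correction_factor_multiplies(self):
        m = AllometricModel(POWER, (2.0, 1.0), cf=1.1)
        assert predict(m, {"x": 3.0}) == pytest.approx(6.6)

    def test_vectorised_over_dataframe(self):
        m = AllometricModel(POWER, (2.0, 2.0))
        out = predict(m, pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out, [2.0, 8.0, 18.0])


class TestCriteria:
    """The four fit criteria in their exact published forms."""

    def test_adjusted_r2(self):
        assert r2_adjusted(1.0, 10, 2) == 1.0
        assert r2_adjusted(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9)
        assert r2_adjusted(0.98, 9, 4) == pytest.approx(0.96)
        with pytest.raises(ValueError):
            r2_adjusted(0.9, 3, 2)

    @given(
        st.floats(min_value=0, max_value=1),
        st.integers(min_value=5, max_value=200),
        st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_adjustment_never_exceeds_r2(self, r2, n, k):
        adj = r2_adjusted(r2, n, k)
        assert adj <= r2 + 1e-12
        if k == 0 or r2 == 1:
            assert adj == pytest.approx(r2)

    def test_rmse_population_divisor(self):
        assert rmse([0, 0, 0]) == 0
        assert rmse([1, -1]) == pytest.approx(1)
        assert rmse([3, 4]) == pytest.approx(math.sqrt(12.5))
        with pytest.raises(ValueError):
            rmse([])

    def test_mpe_sign_means_under_or_overestimate(self):
        assert mpe([5, 7], [5, 7]) == 0
        assert mpe([10, 10], [9, 9]) == pytest.approx(-10.0)
        assert mpe([2, 4, 6], [3, 4, 6]) == pytest.approx(100 * (1 / 3) / 4)
        with pytest.raises(ValueError):
            mpe([1, -1], [0, 0])

    def test_aic_closed_forms(self):
        assert aic(10, 10, 1) == pytest.approx(4.0)
        n = 7
        assert aic(n * math.e, n, 0) == pytest.approx(n + 2)
        assert aic(2.5, 5, 2) == pytest.approx(5 * math.log(0.5) + 6)
        with pytest.warns(UserWarning, match="perfect"):
            assert aic(0.0, 5, 1) == -math.inf

    @given(st.floats(min_value=1e-6, max_value=1e6), st.floats(min_value=1.0001, max_value=10))
    @settings(max_examples=100, derandomize=True)
    def test_aic_monotone_in_sse(self, sse, factor):
        assert aic(sse, 20, 2) < aic(sse * factor, 20, 2)


NOISELESS_CASES = [
    (POWER, (0.05, 3.0), {"x": np.linspace(1, 10, 10)}),
    (QUAD, (1.0, -2.0, 1.0), {"x": np.array([0.0, 1.0, 2.0, 3.0])}),
    (
        LIN2,
        (0.114, 0.005, -0.682),
        {
            "h": np.array([30.0, 45.0, 60.0, 75.0, 90.0, 100.0, 110.0, 120.0]),
            "rho": np.array([0.55, 0.72, 0.61, 0.88, 0.50, 0.79, 0.66, 0.91]),
        },
    ),
    (PMULTI, (0.002, 1.2, 0.8), {"D": np.linspace(1, 8, 12), "h": np.linspace(50, 700, 12)}),
]


class TestFitModel:
    @pytest.mark.parametrize("form,coef,predictors", NOISELESS_CASES, ids=lambda v: getattr(v, "name", ""))
    def test_noiseless_identifiability(self, form, coef, predictors):
        """Zero-noise data generated from each form returns its coefficients."""
        df = pd.DataFrame(predictors)
        truth = AllometricModel(form, coef)
        df["y"] = predict(truth, df)
        fitted = fit_model(form, df)
        assert np.allclose(fitted.coefficients, coef, rtol=1e-6)
        assert fitted.fit.r2_adj == pytest.approx(1.0)

    def test_quadratic_interpolation_exact(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        df["y"] = df.x**2 - 2 * df.x + 1
        fitted = fit_model(QUAD, df)
        assert np.allclose(fitted.coefficients, (1.0, -2.0, 1.0), atol=1e-9)

    def test_beats_brute_force_lattice(self):
        """NLS solution is at least as good as an exhaustive (a, b) grid
        search at step 1e-3 on a 3-point power problem."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.062, 0.29, 0.78])  # near a=0.06, b=2.5 with jitter
        df = pd.DataFrame({"x": x, "y": y})
        fitted = fit_model(POWER, df)

        a_grid = np.arange(0.01, 0.201, 1e-3)
        b_grid = np.arange(1.0, 4.0001, 1e-3)
        pred = a_grid[:, None, None] * x[None, None, :] ** b_grid[None, :, None]
        sse = ((pred - y[None, None, :]) ** 2).sum(axis=2)
        assert fitted.fit.sse <= sse.min() + 1e-12

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"h": [1.0, 2.0, 3.0, 4.0], "rho": [2.0, 4.0, 6.0, 8.0]})
        df["y"] = df.h
        from mangrove_allometry.allometry import FitError

        with pytest.raises(FitError, match="singular"):
            fit_model(LIN2, df)

    def test_power_fit_requires_positive_response(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, -1.0, 2.0]})
        with pytest.raises(ValueError, match="positive"):
            fit_model(POWER, df)


class TestSelectBest:
    def _model(self, aic_v, rmse_v=1.0, r2_adj_v=0.9, n=10):
        fm = compute_fit_metrics([1.0, 2.0, 3.0, 4.0], [1.1, 1.9, 3.2, 3.9], k=1)
        fm = fm.__class__(n=n, k=1, r2=r2_adj_v, r2_adj=r2_adj_v, rmse=rmse_v,
                          mpe_pct=0.0, aic=aic_v, sse=1.0)
        return AllometricModel(POWER, (1.0, 1.0)).with_fit(fm)

    def test_lowest_aic_wins(self):
        best, report = select_best([self._model(17.76), self._model(4.93)])
        assert best.fit.aic == 4.93
        assert list(report["aic"]) == [4.93, 17.76]

    def test_tie_broken_by_rmse(self):
        best, _ = select_best([self._model(5.0, rmse_v=0.41), self._model(5.0, rmse_v=0.16)])
        assert best.fit.rmse == 0.16

    def test_single_candidate_returned(self):
        m = self._model(1.0)
        best, report = select_best([m])
        assert best is m and len(report) == 1

    def test_mixed_datasets_rejected(self):
        with pytest.raises(ValueError, match="different datasets"):
            select_best([self._model(1.0, n=10), self._model(2.0, n=12)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestResidualDiagnostics:
    def test_degenerate_on_noiseless_data(self):
        df = pd.DataFrame({"h": np.linspace(1, 10, 10), "rho": np.linspace(0.4, 0.9, 10)})
        m = AllometricModel(LIN2, (1.0, 2.0, 0.5))
        df["y"] = predict(m, df)
        rep = residual_diagnostics(m, df)
        assert rep["flags"] == ["degenerate"]

    def test_null_residuals_pass_both_checks_usually(self):
        """Normal homoscedastic residuals (n=200) pass Shapiro-Wilk and
        Breusch-Pagan at alpha=0.05 in at least 90% of 100 seeds."""
        passes = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.linspace(1, 10, 200)
            df = pd.DataFrame({"h": x, "rho": rng.uniform(0.4, 0.9, 200)})
            m = AllometricModel(LIN2, (1.0, 2.0, 0.5))
            df["y"] = predict(m, df) + rng.normal(0, 0.5, 200)
            fitted = fit_model(LIN2, df)
            rep = residual_diagnostics(fitted, df)
            if not rep["flags"]:
                passes += 1
        assert passes >= 90

    def test_variance_growing_with_x_flags_heteroscedasticity(self):
        """Residual variance proportional to x^2 trips Breusch-Pagan at
        alpha=0.05 in at least 80% of 100 seeds."""
        trips = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.linspace(1, 10, 200)
            df = pd.DataFrame({"h": x, "rho": rng.uniform(0.4, 0.9, 200)})
            m = AllometricModel(LIN2, (1.0, 2.0, 0.5))
            df["y"] = predict(m, df) + rng.normal(0, 0.2 * x**2)
            fitted = fit_model(LIN2, df)
            rep = residual_diagnostics(fitted, df)
            if rep["homoscedasticity_p"] < 0.05:
                trips += 1
        assert trips >= 80

    def test_too_few_points_unavailable(self):
        df = pd.DataFrame({"h": [1.0, 2.0], "rho": [0.5, 0.6], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            residual_diagnostics(AllometricModel(LIN2, (0.0, 1.0, 0.0)), df)
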