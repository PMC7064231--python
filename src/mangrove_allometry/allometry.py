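"""Allometric model zoo, arithmetic-space least-squares fitting, and the
four fit-selection criteria (adjusted R², RMSE, MPE, AIC).

Model forms
-----------
POWER          y = a·x^b                       (1 predictor, 2 coefficients)
QUADRATIC      y = a·x² + b·x + c              (1 predictor, 3 coefficients)
LINEAR_MULTI   y = a + Σᵢ cᵢ·xᵢ               (intercept + 1 coefficient/predictor)
POWER_MULTI    y = a·Π xᵢ^eᵢ                   (scale + 1 exponent/predictor)

All fits minimise Σ(y_obs − y_pred)² in untransformed (arithmetic) space —
the additive-error convention — so no log-back-transform correction factor
applies. A registry entry may still carry a correction factor ``cf`` (the
above-ground equations were fitted in log space elsewhere); prediction then
multiplies the back-transform by CF.

Errors ``e`` enter SSE/RMSE sign-free; the mean percentage error uses
e = predicted − observed, so a negative MPE means underestimation.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelFormName",
    "ModelForm",
    "AllometricModel",
    "FitMetrics",
    "FitError",
    "predict",
    "fit_model",
    "r2_adjusted",
    "rmse",
    "mpe",
    "aic",
    "compute_fit_metrics",
    "select_best",
    "residual_diagnostics",
]

MAX_ITER = 500
SSE_RTOL = 1e-10
N_RESTARTS = 5


class ModelFormName(str, enum.Enum):
    POWER = "POWER"
    QUADRATIC = "QUADRATIC"
    LINEAR_MULTI = "LINEAR_MULTI"
    POWER_MULTI = "POWER_MULTI"


@dataclass(frozen=True)
class ModelForm:
    """A functional form plus the ordered semantic predictors it consumes.

    Predictors are drawn from {x (root basal diameter, cm), D (stem
    diameter, cm), h (height, cm), V (crown volume, cm³), rho (wood
    density, g cm⁻³)}.
    """

    name: ModelFormName
    predictor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name in (ModelFormName.POWER, ModelFormName.QUADRATIC):
            if len(self.predictor_names) != 1:
                raise ValueError(f"{self.name.value} takes exactly one predictor")
        elif not self.predictor_names:
            raise ValueError(f"{self.name.value} needs at least one predictor")

    @property
    def n_coefficients(self) -> int:
        if self.name == ModelFormName.POWER:
            return 2
        if self.name == ModelFormName.QUADRATIC:
            return 3
        return 1 + len(self.predictor_names)


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary for one fitted model.

    ``k`` counts independent variables (predictors), not coefficients.
    ``r2`` is 1 − SSE/SStot about the observed mean (pseudo-R² for the
    nonlinear forms). ``mpe_pct`` is signed: negative = underestimation.
    """

    n: int
    k: int
    r2: float
    r2_adj: float
    rmse: float
    mpe_pct: float
    aic: float
    sse: float


@dataclass(frozen=True)
class AllometricModel:
    """A functional form with fitted or published coefficients.

    ``scope`` is a (height_class, compartment) label or "GENERALIST";
    ``cf`` is a log-back-transform correction factor applied
    multiplicatively at prediction time (published above-ground equations
    only; None for everything fitted here).
    """

    form: ModelForm
    coefficients: tuple[float, ...]
    response: str = "dry mass (kg)"
    scope: tuple[str, str] | str | None = None
    fit: FitMetrics | None = None
    cf: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.form.n_coefficients:
            raise ValueError(
                f"{self.form.name.value} needs {self.form.n_coefficients} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def with_fit(self, metrics: FitMetrics) -> "AllometricModel":
        return replace(self, fit=metrics)


class FitError(RuntimeError):
    """Fit failure; carries the best parameters seen so far."""

    def __init__(self, message: str, best_coefficients=None, best_sse=None):
        super().__init__(message)
        self.best_coefficients = best_coefficients
        self.best_sse = best_sse


def _eval_form(name: ModelFormName, coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Evaluate a form on an (n, p) predictor matrix."""
    if name == ModelFormName.POWER:
        a, b = coef
        return a * X[:, 0] ** b
    if name == ModelFormName.QUADRATIC:
        a, b, c = coef
        x = X[:, 0]
        return a * x**2 + b * x + c
    if name == ModelFormName.LINEAR_MULTI:
        return coef[0] + X @ coef[1:]
    if name == ModelFormName.POWER_MULTI:
        return coef[0] * np.prod(X ** coef[1:], axis=1)
    raise ValueError(name)


def predict(model: AllometricModel, predictors: dict[str, float] | pd.DataFrame) -> float | np.ndarray:
    """Predict the response (dry mass, kg) from named predictor values.

    Accepts a scalar mapping or a DataFrame; missing predictors raise by
    name, and non-positive bases under fractional exponents raise rather
    than return complex masses. If the model carries a correction factor
    the prediction is multiplied by it.
    """
    scalar = not isinstance(predictors, pd.DataFrame)
    frame = pd.DataFrame([predictors]) if scalar else predictors
    missing = [p for p in model.form.predictor_names if p not in frame.columns]
    if missing:
        raise KeyError(f"missing predictor(s) {missing} for {model.form.name.value} model")
    X = frame[list(model.form.predictor_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    coef = np.asarray(model.coefficients, dtype=float)
    if model.form.name in (ModelFormName.POWER, ModelFormName.POWER_MULTI):
        exponents = coef[1:]
        fractional = exponents != np.round(exponents)
        bases = X if model.form.name == ModelFormName.POWER_MULTI else X[:, :1]
        if np.any((bases <= 0) & fractional[np.newaxis, :]):
            raise ValueError("non-positive predictor under a fractional exponent")
    y = _eval_form(model.form.name, coef, X)
    if model.cf is not None:
        y = y * model.cf
    return float(y[0]) if scalar else y


def r2_adjusted(r2: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination
    R²adj = 1 − (1 − R²)(n − 1)/(n − k − 1); needs n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, k={k} (need n > k+1)")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def rmse(residuals) -> float:
    """Root mean square error sqrt(Σe²/n), population divisor n."""
    e = np.asarray(residuals, dtype=float)
    if e.size == 0:
        raise ValueError("RMSE of an empty residual vector")
    return float(np.sqrt(np.mean(e**2)))


def mpe(observed, predicted) -> float:
    """Mean percentage error 100·(Σe/n)/mean(observed), e = predicted − observed.

    Negative values indicate underestimation, positive overestimation.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    m_obs = obs.mean()
    if m_obs == 0:
        raise ValueError("MPE undefined for zero mean observed response")
    e = pred - obs
    return float(e.mean() / m_obs * 100.0)


def aic(sse: float, n: int, k: int, c: float = 0.0) -> float:
    """Akaike information criterion n·ln(SSE/n) + 2(k+1) + c.

    ``k`` is the number of independent variables; ``c`` is an additive
    constant (default 0 — it cancels within any candidate set fitted to the
    same data). A perfect fit (SSE = 0) returns −inf with a warning.
    """
    if n < 1:
        raise ValueError("AIC needs n >= 1")
    if sse < 0:
        raise ValueError("SSE must be non-negative")
    if sse == 0:
        warnings.warn("AIC of a perfect fit (SSE = 0): returning -inf", stacklevel=2)
        return float("-inf")
    return float(n * math.log(sse / n) + 2.0 * (k + 1) + c)


def compute_fit_metrics(observed, predicted, k: int, aic_constant: float = 0.0) -> FitMetrics:
    """All four criteria for one model on its fitting data."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    e = obs - pred
    sse = float(np.sum(e**2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = aic(sse, n, k, aic_constant)
    return FitMetrics(
        n=n,
        k=k,
        r2=r2,
        r2_adj=r2_adjusted(r2, n, k),
        rmse=rmse(e),
        mpe_pct=mpe(obs, pred),
        aic=a,
        sse=sse,
    )


def _auto_init(form: ModelForm, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Starting coefficients: log-log OLS for power forms, exact normal
    equations for the linear-in-coefficients forms."""
    name = form.name
    if name == ModelFormName.QUADRATIC:
        A = np.column_stack([X[:, 0] ** 2, X[:, 0], np.ones_like(y)])
        return np.linalg.lstsq(A, y, rcond=None)[0]
    if name == ModelFormName.LINEAR_MULTI:
        A = np.column_stack([np.ones_like(y), X])
        return np.linalg.lstsq(A, y, rcond=None)[0]
    # power forms: fit ln y = ln a + Σ b_i ln x_i on the positive subset
    ok = (y > 0) & np.all(X > 0, axis=1)
    if ok.sum() >= form.n_coefficients:
        A = np.column_stack([np.ones(int(ok.sum())), np.log(X[ok])])
        beta = np.linalg.lstsq(A, np.log(y[ok]), rcond=None)[0]
        return np.concatenate([[math.exp(beta[0])], beta[1:]])
    return np.concatenate([[max(float(np.mean(np.abs(y))), 1e-6)], np.ones(len(form.predictor_names))])


def fit_model(
    form: ModelForm,
    data: pd.DataFrame,
    response: str = "y",
    init: np.ndarray | str = "AUTO",
    aic_constant: float = 0.0,
    seed: int = 0,
) -> AllometricModel:
    """Fit a candidate form by nonlinear least squares in arithmetic space.

    ``data`` holds one column per predictor plus the response column.
    Coefficients minimise Σ(y_obs − y_pred)²; convergence is a relative SSE
    change below 1e-10 within 500 iterations, with 5 deterministic jittered
    restarts before declaring failure. The returned model carries populated
    :class:`FitMetrics`.
    """
    missing = [p for p in form.predictor_names if p not in data.columns]
    if missing:
        raise KeyError(f"data lacks predictor column(s) {missing}")
    if response not in data.columns:
        raise KeyError(f"data lacks response column {response!r}")
    X = data[list(form.predictor_names)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    n = y.size
    if n < form.n_coefficients + 1:
        raise ValueError(f"need at least {form.n_coefficients + 1} rows to fit {form.name.value}")
    if form.name in (ModelFormName.POWER, ModelFormName.POWER_MULTI) and np.any(y <= 0):
        raise ValueError("power-form fits require strictly positive responses")

    if form.name == ModelFormName.LINEAR_MULTI:
        A = np.column_stack([np.ones_like(y), X])
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise FitError("singular design matrix for LINEAR_MULTI fit")

    x0 = _auto_init(form, X, y) if isinstance(init, str) else np.asarray(init, dtype=float)

    def residuals(coef: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            pred = _eval_form(form.name, coef, X)
        return np.where(np.isfinite(pred), pred - y, 1e150) if not np.all(np.isfinite(pred)) else pred - y

    rng = np.random.default_rng(seed)
    best: optimize.OptimizeResult | None = None
    start = x0
    for attempt in range(N_RESTARTS + 1):
        try:
            res = optimize.least_squares(
                residuals, start, method="lm" if n >= start.size else "trf",
                xtol=SSE_RTOL, ftol=SSE_RTOL, gtol=SSE_RTOL, max_nfev=MAX_ITER * (start.size + 1),
            )
        except Exception:
            res = None
        if res is not None and np.all(np.isfinite(res.x)):
            if best is None or res.cost < best.cost:
                best = res
            if res.success:
                break
        start = x0 * (1.0 + 0.2 * rng.standard_normal(x0.size)) + 1e-3 * rng.standard_normal(x0.size)
    if best is None:
        raise FitError(f"{form.name.value} fit failed to converge after {N_RESTARTS} restarts")

    coef = best.x
    pred = _eval_form(form.name, coef, X)
    metrics = compute_fit_metrics(y, pred, k=len(form.predictor_names), aic_constant=aic_constant)
    return AllometricModel(form=form, coefficients=tuple(float(v) for v in coef), fit=metrics)


def select_best(candidates: list[AllometricModel]) -> tuple[AllometricModel, pd.DataFrame]:
    """Rank fitted candidates by AIC (ascending), breaking ties by RMSE
    then by adjusted R² (descending); returns (winner, ranking table).

    Candidates must all be fitted on the same data (checked via n).
    """
    if not candidates:
        raise ValueError("no candidate models to select from")
    if any(m.fit is None for m in candidates):
        raise ValueError("all candidates must carry fit metrics")
    ns = {m.fit.n for m in candidates}
    if len(ns) > 1:
        raise ValueError(f"candidates fitted on different datasets (n values {sorted(ns)})")

    def key(m: AllometricModel):
        return (m.fit.aic, m.fit.rmse, -m.fit.r2_adj)

    ranked = sorted(candidates, key=key)
    # explicit tie handling at 1e-9 on AIC: the sort key above already
    # orders exact ties correctly; near-ties fall back the same way
    for i in range(len(ranked) - 1):
        a, b = ranked[i], ranked[i + 1]
        if abs(a.fit.aic - b.fit.aic) < 1e-9 and (
            b.fit.rmse < a.fit.rmse
            or (b.fit.rmse == a.fit.rmse and b.fit.r2_adj > a.fit.r2_adj)
        ):
            ranked[i], ranked[i + 1] = b, a
    report = pd.DataFrame(
        {
            "form": [m.form.name.value for m in ranked],
            "predictors": ["+".join(m.form.predictor_names) for m in ranked],
            "aic": [m.fit.aic for m in ranked],
            "rmse": [m.fit.rmse for m in ranked],
            "r2_adj": [m.fit.r2_adj for m in ranked],
            "mpe_pct": [m.fit.mpe_pct for m in ranked],
        }
    )
    report.index.name = "rank"
    return ranked[0], report


def residual_diagnostics(model: AllometricModel, data: pd.DataFrame, response: str = "y") -> dict:
    """Shapiro–Wilk normality and Breusch–Pagan homoscedasticity checks on
    the residuals of a fitted model, plus the residual-vs-fitted table.

    Returns ``{"normality_p", "homoscedasticity_p", "table", "flags"}``
    where flags mark p < 0.05 (or "degenerate" when residuals are ~0).
    """
    from statsmodels.stats.diagnostic import het_breuschpagan

    y = data[response].to_numpy(dtype=float)
    if y.size < 3:
        raise ValueError("diagnostics need at least 3 observations")
    fitted = np.asarray(predict(model, data), dtype=float)
    resid = y - fitted
    table = pd.DataFrame({"fitted": fitted, "residual": resid})
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.max(np.abs(resid)) < 1e-10 * scale:
        return {
            "normality_p": None,
            "homoscedasticity_p": None,
            "table": table,
            "flags": ["degenerate"],
        }
    sw_p = float(stats.shapiro(resid).pvalue)
    exog = np.column_stack([np.ones_like(fitted), fitted])
    bp_p = float(het_breuschpagan(resid, exog)[1])
    flags = []
    if sw_p < 0.05:
        flags.append("non-normal residuals")
    if bp_p < 0.05:
        flags.append("heteroscedastic residuals")
    return {"normality_p": sw_p, "homoscedasticity_p": bp_p, "table": table, "flags": flags}
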