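"""Calibration of predicted EP risks: intercept, slope and smoothed curve.

Calibration-in-the-large (CITL) is the intercept of a logistic recalibration
with the slope fixed at 1 (an offset model): positive CITL means the model
under-predicts EP on average, negative means over-prediction.  The
calibration slope is the coefficient of logit(predicted risk) in a free
logistic recalibration: a slope below 1 means predictions are too extreme
(high risks overestimated, low risks underestimated), above 1 too moderate.
The calibration curve is a loess-style local linear regression of the binary
outcome on the predicted risk with tricube weights and pointwise Wald CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .discrimination import DegenerateInputError

_EPS = 1e-12
_MAX_ABS_COEF = 30.0   # recalibration coefficients beyond this signal separation


class FitError(RuntimeError):
    """Recalibration fit failed to converge or separated."""


@dataclass(frozen=True)
class CalibrationSummary:
    citl: float
    citl_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    slope_intercept: float
    slope_intercept_ci: tuple[float, float]
    n: int
    mean_predicted: float
    observed_rate: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Loess-smoothed observed EP proportion over a predicted-risk grid."""

    grid: np.ndarray
    smoothed: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.grid) > 0), "grid must be strictly increasing"

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"predicted": self.grid, "observed_smoothed": self.smoothed,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        ).to_csv(Path(path), index=False)


def logit(p, epsilon: float = _EPS):
    """log(p / (1-p)) with p clipped into [epsilon, 1-epsilon]."""
    p = np.clip(np.asarray(p, dtype=float), epsilon, 1.0 - epsilon)
    return np.log(p / (1.0 - p))


def _check_binary(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and y must be aligned")
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateInputError("need at least one event and one non-event")
    return p, y


def _fit_logistic(y: np.ndarray, exog: np.ndarray, offset=None):
    """IRLS logistic fit via statsmodels GLM with separation guard."""
    model = sm.GLM(y, exog, family=sm.families.Binomial(), offset=offset)
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as e:  # pragma: no cover - statsmodels failure path
        raise FitError(f"logistic recalibration failed: {e}") from e
    if not res.converged:
        raise FitError("logistic recalibration did not converge in 100 iterations")
    if np.any(np.abs(res.params) > _MAX_ABS_COEF):
        raise FitError("separation detected: recalibration coefficients diverged")
    return res


def calibration_in_the_large(p, y, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """CITL: MLE intercept of sigmoid(a + logit(p)) with slope fixed at 1.

    Returns (citl, Wald CI).  Positive values mean the average predicted EP
    risk is below the observed EP rate.
    """
    p, y = _check_binary(p, y)
    res = _fit_logistic(y, np.ones((p.size, 1)), offset=logit(p))
    a = float(res.params[0])
    se = float(res.bse[0])
    z = norm.ppf(0.5 + level / 2.0)
    return a, (a - z * se, a + z * se)


def calibration_slope(p, y, level: float = 0.95) -> tuple[
        tuple[float, tuple[float, float]], tuple[float, tuple[float, float]]]:
    """Free logistic recalibration a + b*logit(p).

    Returns ((intercept, CI), (slope, CI)).  Requires at least two distinct
    predicted values.
    """
    p, y = _check_binary(p, y)
    lp = logit(p)
    if np.ptp(lp) == 0:
        raise DegenerateInputError("calibration slope needs >= 2 distinct predictions")
    exog = np.column_stack([np.ones_like(lp), lp])
    res = _fit_logistic(y, exog)
    z = norm.ppf(0.5 + level / 2.0)
    a, b = (float(v) for v in res.params)
    se_a, se_b = (float(v) for v in res.bse)
    return ((a, (a - z * se_a, a + z * se_a)),
            (b, (b - z * se_b, b + z * se_b)))


def calibration_summary(p, y) -> CalibrationSummary:
    p_arr, y_arr = _check_binary(p, y)
    citl, citl_ci = calibration_in_the_large(p_arr, y_arr)
    (a, a_ci), (b, b_ci) = calibration_slope(p_arr, y_arr)
    return CalibrationSummary(
        citl=citl, citl_ci=citl_ci, slope=b, slope_ci=b_ci,
        slope_intercept=a, slope_intercept_ci=a_ci, n=int(y_arr.size),
        mean_predicted=float(p_arr.mean()), observed_rate=float(y_arr.mean()),
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _local_linear_fit(x: np.ndarray, y: np.ndarray, x0: float, k: int,
                      degree: int) -> tuple[float, float]:
    """Weighted polynomial fit at one query point.

    Returns (fitted value, sandwich variance of the fit).  The bandwidth is
    the distance to the k-th nearest neighbour (loess-style span).
    """
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h == 0:
        h = np.finfo(float).tiny
    w = _tricube(d / h)
    mask = w > 0
    xs, ys, ws = x[mask], y[mask], w[mask]
    # design matrix centred at x0 so the intercept is the fitted value
    cols = [np.ones_like(xs)]
    for dgr in range(1, degree + 1):
        cols.append((xs - x0) ** dgr)
    X = np.column_stack(cols)
    W = ws
    XtW = X.T * W
    A = XtW @ X
    try:
        beta = np.linalg.solve(A, XtW @ ys)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        # all weight on identical x: fall back to the weighted mean
        fit = float(np.average(ys, weights=ws))
        resid = ys - fit
        l = ws / ws.sum()
        return fit, float(np.sum(l**2 * resid**2))
    fit = float(beta[0])
    # influence vector of the fitted value: fit = l @ ys
    l = (Ainv @ XtW)[0]
    resid = ys - X @ beta
    var = float(np.sum(l**2 * resid**2))   # heteroscedasticity-robust
    return fit, var


def loess_calibration_curve(p, y, span: float = 0.75, degree: int = 1,
                            grid_size: int = 100, level: float = 0.95,
                            bootstrap: int = 0, seed: int | None = None) -> CalibrationCurve:
    """Loess-smoothed calibration curve with pointwise CIs.

    ``span`` is the neighbourhood fraction for the tricube kernel; pointwise
    CIs come from the local fit's sandwich variance, or from ``bootstrap``
    resamples when that is positive.  Needs at least 20 observations.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must be in (0, 1], got {span}")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size < 20:
        raise DegenerateInputError("calibration curve needs >= 20 observations")
    lo, hi = float(p.min()), float(p.max())
    if lo == hi:
        raise DegenerateInputError("calibration curve needs non-constant predictions")
    grid = np.linspace(lo, hi, grid_size)
    k = max(degree + 2, int(np.ceil(span * p.size)))
    k = min(k, p.size)

    fits = np.empty(grid_size)
    variances = np.empty(grid_size)
    for i, x0 in enumerate(grid):
        fits[i], variances[i] = _local_linear_fit(p, y, float(x0), k, degree)

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((bootstrap, grid_size))
        idx_all = np.arange(p.size)
        for b in range(bootstrap):
            idx = rng.choice(idx_all, size=p.size, replace=True)
            pb, yb = p[idx], y[idx]
            for i, x0 in enumerate(grid):
                boots[b, i], _ = _local_linear_fit(pb, yb, float(x0), k, degree)
        alpha = 1.0 - level
        ci_lo = np.quantile(boots, alpha / 2, axis=0)
        ci_hi = np.quantile(boots, 1 - alpha / 2, axis=0)
    else:
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(variances)
        ci_lo, ci_hi = fits - half, fits + half

    return CalibrationCurve(
        grid=grid,
        smoothed=np.clip(fits, 0.0, 1.0),
        ci_low=np.clip(ci_lo, 0.0, 1.0),
        ci_high=np.clip(ci_hi, 0.0, 1.0),
        span=span,
    )


def calibration_band_assessment(curve: CalibrationCurve, lo: float, hi: float,
                                tol: float) -> bool:
    """True iff the smoothed curve stays within ``tol`` of the diagonal on
    the grid points falling in [lo, hi] — an operational reading of
    "close to the 45-degree line"."""
    mask = (curve.grid >= lo) & (curve.grid <= hi)
    if not mask.any():
        raise ValueError(f"no grid points in [{lo}, {hi}]")
    return bool(np.all(np.abs(curve.smoothed[mask] - curve.grid[mask]) <= tol))
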