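"""Calibration: offset-model intercept, recalibration slope, loess curve."""

import numpy as np
import pytest
from scipy.special import expit

from pulvalid import (calibration_band_assessment, calibration_in_the_large,
                      calibration_slope, calibration_summary,
                      loess_calibration_curve, logit)
from pulvalid.calibration import _local_linear_fit, _tricube
from pulvalid.discrimination import DegenerateInputError


def const_p_data(p, n, events):
    y = np.zeros(n)
    y[:events] = 1.0
    return np.full(n, p), y


def test_logit_examples():
    assert logit(0.5) == pytest.approx(0.0)
    assert logit(0.75) == pytest.approx(np.log(3.0))
    assert np.isfinite(logit(1.0)) and np.isfinite(logit(0.0))
    assert logit(1.0) == pytest.approx(logit(1.0 - 1e-12))


def test_citl_closed_form_constant_p_underprediction():
    """With constant predictions the offset-model MLE solves
    logit(observed rate) = citl + logit(p) exactly."""
    p, y = const_p_data(0.2, 1000, 300)
    citl, ci = calibration_in_the_large(p, y)
    expected = float(logit(0.3) - logit(0.2))
    assert citl == pytest.approx(expected, abs=1e-8)
    assert expected == pytest.approx(0.539, abs=1e-3)
    assert ci[0] < citl < ci[1]


def test_citl_closed_form_overprediction_is_negative():
    p, y = const_p_data(0.3, 1000, 150)
    citl, _ = calibration_in_the_large(p, y)
    assert citl == pytest.approx(float(logit(0.15) - logit(0.3)), abs=1e-8)
    assert citl < 0


def test_citl_near_zero_when_outcomes_drawn_from_p(rng):
    p = expit(rng.normal(-1.5, 1.2, 50000))
    y = (rng.random(50000) < p).astype(float)
    citl, _ = calibration_in_the_large(p, y)
    assert abs(citl) < 0.05


def test_citl_rejects_degenerate_outcomes():
    with pytest.raises(DegenerateInputError):
        calibration_in_the_large(np.full(10, 0.2), np.ones(10))


def test_slope_two_point_closed_form():
    """Saturated two-point design: slope equals the ratio of observed to
    predicted logit spreads."""
    n = 1000
    p = np.r_[np.full(n, 0.1), np.full(n, 0.4)]
    y = np.r_[np.r_[np.ones(300), np.zeros(n - 300)],
              np.r_[np.ones(500), np.zeros(n - 500)]]
    (a, _), (b, _) = calibration_slope(p, y)
    expected_b = float((logit(0.3) - logit(0.5)) / (logit(0.1) - logit(0.4)))
    expected_a = float(logit(0.3) - expected_b * logit(0.1))
    assert b == pytest.approx(expected_b, abs=1e-6)
    assert a == pytest.approx(expected_a, abs=1e-6)
    assert expected_b == pytest.approx(0.473, abs=1e-3)


def test_slope_unity_when_outcomes_drawn_from_p(rng):
    p = expit(rng.normal(-1.5, 1.2, 50000))
    y = (rng.random(50000) < p).astype(float)
    (a, _), (b, _) = calibration_slope(p, y)
    assert abs(b - 1.0) < 0.05 and abs(a) < 0.05


def test_slope_half_under_doubled_logits(rng):
    """Sharpening scores as logit(p') = 2 logit(p) halves the recalibration
    slope when outcomes are generated from p."""
    p = expit(rng.normal(-1.5, 1.0, 50000))
    y = (rng.random(50000) < p).astype(float)
    sharpened = expit(2.0 * logit(p))
    (_, _), (b, _) = calibration_slope(sharpened, y)
    assert b == pytest.approx(0.5, abs=0.05)


def test_slope_rejects_constant_predictions():
    with pytest.raises(DegenerateInputError, match="distinct"):
        calibration_slope(np.full(100, 0.2), np.r_[np.ones(30), np.zeros(70)])


def test_recalibration_consistency(rng):
    """Re-running the slope fit on recalibrated probabilities returns the
    identity transform."""
    p = expit(rng.normal(-1.0, 0.8, 20000))
    y = (rng.random(20000) < expit(0.4 + 1.6 * logit(p))).astype(float)
    (a, _), (b, _) = calibration_slope(p, y)
    recal = expit(a + b * logit(p))
    (a2, _), (b2, _) = calibration_slope(recal, y)
    assert b2 == pytest.approx(1.0, abs=0.01)
    assert a2 == pytest.approx(0.0, abs=0.01)


def test_summary_fields(rng):
    p = expit(rng.normal(-1.5, 1.0, 5000))
    y = (rng.random(5000) < p).astype(float)
    s = calibration_summary(p, y)
    assert s.n == 5000
    assert s.mean_predicted == pytest.approx(p.mean())
    assert s.observed_rate == pytest.approx(y.mean())
    assert s.slope_ci[0] < s.slope < s.slope_ci[1]


def test_loess_constant_response(rng):
    p = rng.random(200)
    curve = loess_calibration_curve(p, np.ones(200))
    assert np.allclose(curve.smoothed, 1.0)
    curve0 = loess_calibration_curve(p, np.zeros(200))
    assert np.allclose(curve0.smoothed, 0.0)


def test_loess_matches_standalone_wls_oracle(rng):
    """At fixed query points the smoothed value equals an independently
    written tricube-weighted linear least squares fit."""
    p = np.sort(rng.random(80))
    y = (rng.random(80) < p).astype(float)
    span = 0.75
    k = int(np.ceil(span * p.size))
    curve = loess_calibration_curve(p, y, span=span, grid_size=7)
    for idx in (1, 3, 5):
        x0 = curve.grid[idx]
        d = np.abs(p - x0)
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        W = np.diag(w)
        X = np.column_stack([np.ones_like(p), p - x0])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert curve.smoothed[idx] == pytest.approx(
            float(np.clip(beta[0], 0, 1)), abs=1e-8)


def test_loess_rejects_small_samples_and_bad_span(rng):
    with pytest.raises(DegenerateInputError):
        loess_calibration_curve(rng.random(10), np.zeros(10))
    with pytest.raises(ValueError):
        loess_calibration_curve(rng.random(50), np.zeros(50), span=1.5)


def test_loess_curve_csv_round_trip(tmp_path, rng):
    p = rng.random(100)
    y = (rng.random(100) < p).astype(float)
    curve = loess_calibration_curve(p, y)
    path = tmp_path / "curve.csv"
    curve.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns) == ["predicted", "observed_smoothed", "ci_low", "ci_high"]
    assert len(df) == curve.grid.size


def test_band_assessment():
    from pulvalid.calibration import CalibrationCurve
    grid = np.linspace(0.01, 0.5, 50)
    diag = CalibrationCurve(grid=grid, smoothed=grid.copy(),
                            ci_low=grid, ci_high=grid, span=0.75)
    assert calibration_band_assessment(diag, 0.0, 0.2, tol=0.0)
    shifted = CalibrationCurve(grid=grid, smoothed=np.clip(grid + 0.1, 0, 1),
                               ci_low=grid, ci_high=grid, span=0.75)
    assert not calibration_band_assessment(shifted, 0.0, 0.2, tol=0.05)
    with pytest.raises(ValueError):
        calibration_band_assessment(diag, 0.9, 0.95, tol=0.1)


def test_tricube_kernel_shape():
    u = np.array([0.0, 0.5, 1.0, 1.5])
    w = _tricube(u)
    assert w[0] == 1.0 and w[2] == 0.0 and w[3] == 0.0
    assert 0 < w[1] < 1
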