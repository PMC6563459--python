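"""Rolling nowcast-validation protocol.

Holds out the final years of each observed series, refits on the shortened
window, nowcasts the held-out years, and summarises percent errors per area
and nationally — including a calibration regression of nowcasted on measured
values and a drift-free random-walk baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Window",
    "ValidationReport",
    "make_windows",
    "percent_error",
    "summarize_errors",
    "calibration_regression",
    "random_walk_baseline",
]


class InsufficientSpanError(ValueError):
    """Raised when the panel does not cover enough years for the protocol."""


@dataclass(frozen=True)
class Window:
    """One rolling validation window."""

    train_start: int
    train_end: int  # inclusive
    target_year: int
    horizon: int

    @property
    def label(self) -> str:
        return f"h{self.horizon}"


@dataclass
class ValidationReport:
    """Per-area and aggregate nowcast errors plus baseline comparison."""

    per_area_errors: dict  # window label -> {area_id: percent error}
    national_errors: dict  # window label -> percent error
    summaries: dict  # window label -> summary dict
    calibration_slope: float
    calibration_r2: float
    model_rmse: float
    model_mae: float
    baseline_rmse: float
    baseline_mae: float


def make_windows(panel_years) -> list[Window]:
    """The four rolling windows of the validation protocol.

    With a 13-year panel keyed ``y0 .. y0+12`` the windows are: train on the
    first 10 years and nowcast 1, 2 and 3 years ahead, and train on the first
    8 years and nowcast the final year 5 ahead.
    """
    years = sorted(int(y) for y in panel_years)
    if len(years) < 13:
        raise InsufficientSpanError(
            f"panel spans {len(years)} years; the protocol needs at least 13"
        )
    if years != list(range(years[0], years[0] + len(years))):
        raise InsufficientSpanError("panel years are not contiguous")
    y0 = years[0]
    return [
        Window(y0, y0 + 9, y0 + 10, 1),
        Window(y0, y0 + 9, y0 + 11, 2),
        Window(y0, y0 + 9, y0 + 12, 3),
        Window(y0, y0 + 7, y0 + 12, 5),
    ]


def percent_error(predicted: float, measured: float) -> float:
    """Signed percent error ``100 * (predicted - measured) / measured``."""
    if measured <= 0:
        raise ValueError(f"measured value must be positive, got {measured}")
    return 100.0 * (predicted - measured) / measured


def summarize_errors(per_area_errors) -> dict:
    """Median, IQR (linear-interpolation quantiles), range and within-10% count."""
    e = np.asarray(list(per_area_errors), dtype=float)
    if e.size == 0:
        raise ValueError("no errors to summarize")
    q25, q50, q75 = np.percentile(e, [25, 50, 75])
    return {
        "median": float(q50),
        "iqr_low": float(q25),
        "iqr_high": float(q75),
        "min": float(e.min()),
        "max": float(e.max()),
        "within_10pct_count": int(np.sum(np.abs(e) <= 10.0)),
        "n_areas": int(e.size),
    }


def calibration_regression(nowcasted, measured) -> tuple[float, float]:
    """OLS of nowcasted (response) on measured (predictor), with intercept.

    Returns ``(slope, r_squared)``.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(nowcasted, dtype=float)
    if len(x) < 3:
        raise ValueError("at least 3 areas required for the calibration regression")
    if np.var(x) == 0:
        raise ValueError("degenerate regression: measured values have zero variance")
    result = sps.linregress(x, y)
    return float(result.slope), float(result.rvalue**2)


def random_walk_baseline(training_series, horizon: int) -> np.ndarray:
    """Drift-free random-walk point forecast: the last observed value, repeated."""
    y = np.asarray(training_series, dtype=float)
    if y.size == 0:
        raise ValueError("empty training series")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return np.full(horizon, y[-1])


def build_report(
    predictions: dict,
    measurements: dict,
    baseline_predictions: dict,
    calibration_window_label: str = "h5",
) -> ValidationReport:
    """Assemble a :class:`ValidationReport` from per-window prediction maps.

    Parameters
    ----------
    predictions, measurements, baseline_predictions
        Nested maps ``window label -> {area_id: value}``; the model and
        baseline entries are point nowcasts of the window's target year.
    calibration_window_label
        Window whose per-area nowcasts feed the calibration regression.
    """
    per_area_errors: dict = {}
    national_errors: dict = {}
    summaries: dict = {}
    model_sq, model_abs, base_sq, base_abs = [], [], [], []
    for label, preds in predictions.items():
        meas = measurements[label]
        errors = {a: percent_error(preds[a], meas[a]) for a in preds}
        per_area_errors[label] = errors
        national_errors[label] = percent_error(
            sum(preds.values()), sum(meas.values())
        )
        summaries[label] = summarize_errors(errors.values())
        for a in preds:
            model_sq.append((preds[a] - meas[a]) ** 2)
            model_abs.append(abs(preds[a] - meas[a]))
            base = baseline_predictions[label][a]
            base_sq.append((base - meas[a]) ** 2)
            base_abs.append(abs(base - meas[a]))

    cal = predictions[calibration_window_label]
    cal_meas = measurements[calibration_window_label]
    areas = sorted(cal)
    slope, r2 = calibration_regression(
        [cal[a] for a in areas], [cal_meas[a] for a in areas]
    )
    return ValidationReport(
        per_area_errors=per_area_errors,
        national_errors=national_errors,
        summaries=summaries,
        calibration_slope=slope,
        calibration_r2=r2,
        model_rmse=float(np.sqrt(np.mean(model_sq))),
        model_mae=float(np.mean(model_abs)),
        baseline_rmse=float(np.sqrt(np.mean(base_sq))),
        baseline_mae=float(np.mean(base_abs)),
    )
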