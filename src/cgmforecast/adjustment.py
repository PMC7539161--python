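"""No-intervention trend adjustment.

Models trained on free-living history absorb the patient's own past
corrections: near the range edges they learn that glucose "comes back on its
own", which is exactly when a user should not be reassured.  The adjustment
blends the model's anchors with a linear-regression extrapolation of the
recent CGM trend — a forecast guaranteed to continue the excursion — but
only when all three of these hold:

* glucose is trending toward the outside of the 70-180 mg/dL target range
  (regression slope aimed at the nearer boundary and the projected 30-min
  linear value outside the range);
* the trend direction has not changed recently (no sign change of the
  smoothed slope within the last 20 min — a reversal suggests an unreported
  meal or bolus already acting);
* no meal or insulin event was reported in the last 40 min.

Exercise and app-session events do not veto the adjustment.  The blend
weight on the linear forecast grows with horizon (0.25 at +15 min to 0.6 at
+60 min by default): the further out, the more the learned behaviour embeds
past corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    EventRecord,
    GlucoseSeries,
    PatientProfile,
    JITTER_TOL,
    SENSOR_MAX,
    SENSOR_MIN,
)
from .forecast import HORIZONS, PredictionCurve, interpolate_curve


class TrendUnavailableError(ValueError):
    """Raised when the regression window has too few samples or crosses a gap."""


#: Default weight on the linear forecast at each horizon (minutes -> weight).
def default_weight_schedule() -> dict[int, float]:
    return {h: 0.25 + (0.6 - 0.25) * (h - 15) / 45.0 for h in HORIZONS}


@dataclass
class AdjustmentConfig:
    regression_window: float = 30.0   # minutes of CGM behind t0 for the OLS line
    projection_horizon: float = 30.0  # minutes ahead for the trending-out test
    event_veto_window: float = 40.0   # minutes: meal/insulin lookback
    direction_window: float = 20.0    # minutes scanned for a slope sign change
    smooth_window: float = 15.0       # minutes of moving average before slopes
    weights: dict[int, float] = field(default_factory=default_weight_schedule)


@dataclass
class AdjustmentDecision:
    """Outcome of the three-condition test plus the per-horizon blend weights."""

    apply: bool
    trending_out: bool
    no_direction_change: bool
    no_recent_events: bool
    weight_linear: dict[int, float] = field(default_factory=dict)

    @property
    def reasons(self) -> dict[str, bool]:
        return {
            "trending_out": self.trending_out,
            "no_direction_change": self.no_direction_change,
            "no_recent_events": self.no_recent_events,
        }


def _window_arrays(
    series: GlucoseSeries, t0, window: float
) -> tuple[np.ndarray, np.ndarray]:
    """(minutes-relative-to-t0, values) over the trailing window ending at t0."""
    i = series.index_of(t0)
    if i < 0:
        raise TrendUnavailableError(f"no sample at {t0}")
    mins = series.minutes()
    lo = int(np.searchsorted(mins, mins[i] - window - 1e-9))
    t = mins[lo : i + 1] - mins[i]
    v = series.values[lo : i + 1]
    # a gap inside the window shows up as a spacing jump
    if len(t) >= 2 and np.any(np.diff(t) > series.step * 3 + JITTER_TOL):
        raise TrendUnavailableError("regression window crosses a data gap")
    return t, v


def linear_trend_forecast(series: GlucoseSeries, t0, horizon: float,
                          window: float = 30.0) -> float:
    """OLS line through the recent window, evaluated ``horizon`` min ahead.

    Clamped to the sensor range.  Needs at least 4 samples in the window.
    """
    t, v = _window_arrays(series, t0, window)
    if len(t) < 4:
        raise TrendUnavailableError(
            f"linear trend needs >= 4 samples in the {window}-minute window, got {len(t)}"
        )
    slope, intercept = np.polyfit(t, v, 1)
    return float(np.clip(intercept + slope * horizon, SENSOR_MIN, SENSOR_MAX))


def _smoothed_slopes(series: GlucoseSeries, t0, config: AdjustmentConfig) -> np.ndarray:
    """Per-step slopes of the moving-average-smoothed series over the
    direction window ending at t0 (mg/dL per minute)."""
    span = config.direction_window + config.smooth_window
    t, v = _window_arrays(series, t0, span)
    if len(t) < 3:
        return np.empty(0)
    k = max(1, int(round(config.smooth_window / series.step)))
    kernel = np.ones(k) / k
    smooth = np.convolve(v, kernel, mode="valid")  # trailing alignment
    ts = t[k - 1 :]
    keep = ts >= -config.direction_window - 1e-9
    smooth, ts = smooth[keep], ts[keep]
    if len(smooth) < 2:
        return np.empty(0)
    return np.diff(smooth) / np.diff(ts)


def should_adjust(
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    profile: PatientProfile,
    t0,
    config: AdjustmentConfig | None = None,
) -> AdjustmentDecision:
    """Evaluate the three no-intervention conditions at ``t0``."""
    config = config or AdjustmentConfig()
    t064 = np.datetime64(pd.Timestamp(t0), "s")

    # condition 3: no meal or insulin reported in (t0 - 40 min, t0]
    no_recent_events = True
    for ev in events:
        if ev.kind not in ("meal", "bolus", "basal"):
            continue
        back = (t064 - np.datetime64(ev.t, "s")) / np.timedelta64(60, "s")
        if 0 <= back < config.event_veto_window:
            no_recent_events = False
            break

    # condition 1: slope aimed at the nearer boundary and the projected
    # linear value outside the target range
    trending_out = False
    try:
        t, v = _window_arrays(series, t0, config.regression_window)
        if len(t) >= 4:
            slope, intercept = np.polyfit(t, v, 1)
            projected = intercept + slope * config.projection_horizon
            if slope > 0 and projected > profile.target_high:
                trending_out = True
            elif slope < 0 and projected < profile.target_low:
                trending_out = True
    except TrendUnavailableError:
        pass

    # condition 2: no sign change of the smoothed slope in the last 20 min
    no_direction_change = True
    try:
        slopes = _smoothed_slopes(series, t0, config)
        tol = 0.05  # mg/dL per min; drift below this is not a direction
        signs = np.sign(slopes[np.abs(slopes) > tol])
        if len(signs) >= 2 and np.any(signs[1:] != signs[:-1]):
            no_direction_change = False
    except TrendUnavailableError:
        pass

    apply = trending_out and no_direction_change and no_recent_events
    return AdjustmentDecision(
        apply=apply,
        trending_out=trending_out,
        no_direction_change=no_direction_change,
        no_recent_events=no_recent_events,
        weight_linear=dict(config.weights),
    )


def blend_predictions(model_anchor: float, linear_anchor: float, weight_linear: float) -> float:
    """Convex blend: weight_linear * linear + (1 - weight_linear) * model."""
    if not 0.0 <= weight_linear <= 1.0:
        raise ValueError(f"weight_linear must lie in [0, 1], got {weight_linear}")
    return weight_linear * linear_anchor + (1.0 - weight_linear) * model_anchor


def apply_adjustment(
    curve: PredictionCurve,
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    profile: PatientProfile,
    config: AdjustmentConfig | None = None,
) -> PredictionCurve:
    """Return the curve with blended anchors when the conditions fire,
    otherwise the input curve unchanged (adjusted=False)."""
    config = config or AdjustmentConfig()
    decision = should_adjust(series, events, profile, curve.t0, config)
    if not decision.apply:
        return curve
    anchors = {}
    for h in HORIZONS:
        linear = linear_trend_forecast(series, curve.t0, h, config.regression_window)
        anchors[h] = blend_predictions(curve.anchors[h], linear, decision.weight_linear[h])
    return PredictionCurve(
        t0=curve.t0,
        current=curve.current,
        anchors=anchors,
        interpolated=interpolate_curve(curve.current, anchors),
        adjusted=True,
    )
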