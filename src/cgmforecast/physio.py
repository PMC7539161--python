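"""Insulin-on-board / carbs-on-board estimation and model feature assembly.

The on-board quantities follow the usual bolus-calculator semantics: after a
dose (or meal) the undigested remainder decays to zero over the insulin
action duration ``dia`` (carb absorption duration ``cad``).  The default
kinetics are linear — remaining = dose * max(0, 1 - elapsed/duration) — which
is the simplest curve that conserves the dose (the time-integral of the
utilisation rate equals the dose) and reaches exactly zero at the duration.
The curve is a pluggable strategy; a bi-exponential variant can be swapped in
without touching the feature code.

Only ``bolus`` events contribute to IOB (basal is background insulin) and
only ``meal`` events to COB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    EventRecord,
    GlucoseSeries,
    PatientProfile,
    DEFAULT_MAX_GAP,
    JITTER_TOL,
    gap_free_segments,
)

DEFAULT_DIA = 240.0  # minutes; typical rapid-acting insulin action duration
DEFAULT_CAD = 180.0  # minutes; typical mixed-meal absorption duration
N_MIN_EVENTS = 25    # events needed before personalising dia/cad


class FeatureUnavailableError(ValueError):
    """Raised when the requested history window crosses a data gap."""


@dataclass
class PhysioParams:
    """Per-patient physiological kinetics parameters.

    dia/cad in minutes; icr in g/U; cf in mg/dL per U.  ``personalized``
    records whether dia/cad were fitted from this patient's history or are
    population defaults.
    """

    dia: float = DEFAULT_DIA
    cad: float = DEFAULT_CAD
    icr: float = 10.0
    cf: float = 40.0
    personalized: bool = False

    def __post_init__(self) -> None:
        if self.dia <= 0 or self.cad <= 0:
            raise ConfigError("dia and cad must be positive")

    def to_dict(self) -> dict:
        return {
            "dia": self.dia,
            "cad": self.cad,
            "icr": self.icr,
            "cf": self.cf,
            "personalized": self.personalized,
        }


@dataclass
class OnBoardState:
    """Instantaneous on-board amounts and utilisation rates."""

    iob: float = 0.0       # U remaining
    cob: float = 0.0       # g remaining
    iob_rate: float = 0.0  # U/min currently acting
    cob_rate: float = 0.0  # g/min currently absorbing


@dataclass
class FeatureConfig:
    """Feature-window layout shared by training and prediction."""

    history: float = 60.0         # minutes of glucose lags
    activity_window: float = 60.0  # minutes of exercise lookback
    max_gap: float = DEFAULT_MAX_GAP

    def n_lags(self, step: float) -> int:
        return int(round(self.history / step))

    def n_features(self, step: float) -> int:
        n = self.n_lags(step)
        return n + (n - 1) + 4 + 2 + 1 + 1

    def names(self, step: float) -> list[str]:
        n = self.n_lags(step)
        return (
            [f"lag_{i}" for i in range(n)]
            + [f"diff_{i}" for i in range(1, n)]
            + ["iob", "cob", "iob_rate", "cob_rate", "tod_sin", "tod_cos", "day_of_week", "activity"]
        )


@dataclass
class FeatureVector:
    """A fixed-layout model input: values plus their names."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _event_minutes(events: Sequence[EventRecord], origin: np.datetime64) -> np.ndarray:
    return np.array(
        [(np.datetime64(e.t, "s") - origin) / np.timedelta64(60, "s") for e in events], dtype=float
    )


def linear_remaining(elapsed: np.ndarray, duration: float) -> np.ndarray:
    """Fraction of a dose still on board under linear decay; 0 outside [0, duration)."""
    frac = 1.0 - elapsed / duration
    return np.where((elapsed >= 0) & (elapsed < duration), frac, 0.0)


def linear_rate(elapsed: np.ndarray, duration: float) -> np.ndarray:
    """Utilisation rate fraction (per minute) under linear decay."""
    return np.where((elapsed >= 0) & (elapsed < duration), 1.0 / duration, 0.0)


DecayCurve = Callable[[np.ndarray, float], np.ndarray]


def onboard_arrays(
    events: Sequence[EventRecord],
    times: np.ndarray,
    params: PhysioParams,
    remaining_curve: DecayCurve = linear_remaining,
    rate_curve: DecayCurve = linear_rate,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (iob, cob, iob_rate, cob_rate) at each of ``times``."""
    times = np.asarray(times, dtype="datetime64[s]")
    n = len(times)
    iob = np.zeros(n)
    cob = np.zeros(n)
    iob_rate = np.zeros(n)
    cob_rate = np.zeros(n)
    if not events or n == 0:
        return iob, cob, iob_rate, cob_rate
    origin = times[0]
    tmin = (times - origin) / np.timedelta64(60, "s")
    for ev in events:
        e = (np.datetime64(ev.t, "s") - origin) / np.timedelta64(60, "s")
        elapsed = tmin - e
        if ev.kind == "bolus":
            if ev.insulin_units < 0:
                raise ValueError("negative insulin dose")
            iob += ev.insulin_units * remaining_curve(elapsed, params.dia)
            iob_rate += ev.insulin_units * rate_curve(elapsed, params.dia)
        elif ev.kind == "meal":
            if ev.carbs < 0:
                raise ValueError("negative carbs")
            cob += ev.carbs * remaining_curve(elapsed, params.cad)
            cob_rate += ev.carbs * rate_curve(elapsed, params.cad)
    return iob, cob, iob_rate, cob_rate


def estimate_iob(events: Sequence[EventRecord], t, params: PhysioParams) -> OnBoardState:
    """Insulin-on-board at time ``t`` under the configured decay curve."""
    times = np.array([np.datetime64(pd.Timestamp(t), "s")])
    iob, _, iob_rate, _ = onboard_arrays(events, times, params)
    return OnBoardState(iob=float(iob[0]), iob_rate=float(iob_rate[0]))


def estimate_cob(events: Sequence[EventRecord], t, params: PhysioParams) -> OnBoardState:
    """Carbs-on-board at time ``t`` under the configured absorption curve."""
    times = np.array([np.datetime64(pd.Timestamp(t), "s")])
    _, cob, _, cob_rate = onboard_arrays(events, times, params)
    return OnBoardState(cob=float(cob[0]), cob_rate=float(cob_rate[0]))


def simple_onboard_estimate(
    events: Sequence[EventRecord],
    series: GlucoseSeries,
    profile: PatientProfile,
    t=None,
) -> OnBoardState:
    """Fallback on-board estimate for patients without personalised kinetics.

    Each event's remainder is the dose discounted by the glucose change
    observed since the event, relative to the event's expected total effect:
    a meal of ``c`` g is expected to raise glucose by ``c * cf / icr`` mg/dL,
    a bolus of ``u`` U to lower it by ``u * cf``.  The expressed fraction is
    floored at 0 and capped at 1, so the estimate never leaves [0, dose].
    """
    if profile.icr <= 0 or profile.cf <= 0:
        raise ConfigError("profile icr and cf are required for the simple on-board estimate")
    if len(series) == 0:
        return OnBoardState()
    t64 = np.datetime64(pd.Timestamp(t), "s") if t is not None else series.times[-1]
    i_now = int(np.searchsorted(series.times, t64, side="right")) - 1
    if i_now < 0:
        return OnBoardState()
    g_now = series.values[i_now]
    state = OnBoardState()
    for ev in events:
        e64 = np.datetime64(ev.t, "s")
        if e64 > t64:
            continue
        j = int(np.searchsorted(series.times, e64))
        if j >= len(series):
            continue
        g_event = series.values[j]
        delta = g_now - g_event
        if ev.kind == "meal" and ev.carbs > 0:
            expected_rise = ev.carbs * profile.cf / profile.icr
            expressed = min(1.0, max(0.0, delta) / expected_rise)
            state.cob += ev.carbs * (1.0 - expressed)
        elif ev.kind == "bolus" and ev.insulin_units > 0:
            expected_fall = ev.insulin_units * profile.cf
            expressed = min(1.0, max(0.0, -delta) / expected_fall)
            state.iob += ev.insulin_units * (1.0 - expressed)
    # nominal utilisation rates for the remainders under default durations
    state.iob_rate = state.iob / DEFAULT_DIA
    state.cob_rate = state.cob / DEFAULT_CAD
    return state


DIA_GRID = np.arange(120.0, 361.0, 30.0)
CAD_GRID = np.arange(90.0, 301.0, 30.0)


def _clean_event_count(series: GlucoseSeries, events: Sequence[EventRecord], follow: float = 30.0) -> int:
    """Meal/bolus events that fall inside a gap-free segment with ``follow``
    minutes of subsequent coverage — the traces usable for fitting."""
    segments = gap_free_segments(series)
    count = 0
    for ev in events:
        if ev.kind not in ("meal", "bolus"):
            continue
        e64 = np.datetime64(ev.t, "s")
        for i0, i1 in segments:
            if series.times[i0] <= e64 and (series.times[i1] - e64) / np.timedelta64(60, "s") >= follow:
                count += 1
                break
    return count


def fit_physio_params(
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    profile: PatientProfile,
    n_min: int = N_MIN_EVENTS,
) -> PhysioParams:
    """Personalise dia/cad by grid search on a linear glucose-response model.

    For each (dia, cad) candidate the one-step glucose change is regressed on
    the implied carb-absorption and insulin-action rates; the pair minimising
    the residual sum of squares wins.  Falls back to population defaults
    (personalized=False) when fewer than ``n_min`` clean meal/bolus traces
    exist.
    """
    defaults = PhysioParams(icr=profile.icr, cf=profile.cf, personalized=False)
    if len(series) < 3 or _clean_event_count(series, events) < n_min:
        return defaults

    dt = np.diff(series.times) / np.timedelta64(60, "s")
    step_ok = np.abs(dt - series.step) <= JITTER_TOL
    if step_ok.sum() < 10:
        return defaults
    dg = np.diff(series.values)[step_ok]

    best = (np.inf, defaults.dia, defaults.cad)
    for dia in DIA_GRID:
        for cad in CAD_GRID:
            p = PhysioParams(dia=dia, cad=cad, icr=profile.icr, cf=profile.cf)
            _, _, iob_rate, cob_rate = onboard_arrays(events, series.times, p)
            X = np.column_stack(
                [np.ones(step_ok.sum()), cob_rate[:-1][step_ok], iob_rate[:-1][step_ok]]
            )
            coef, _, _, _ = np.linalg.lstsq(X, dg, rcond=None)
            sse = float(np.sum((dg - X @ coef) ** 2))
            if sse < best[0] - 1e-9:
                best = (sse, dia, cad)
    return PhysioParams(dia=best[1], cad=best[2], icr=profile.icr, cf=profile.cf, personalized=True)


def _activity_summary(events: Sequence[EventRecord], t64: np.datetime64, window: float) -> float:
    """Ordinal activity feature: max exercise intensity in the lookback window."""
    best = 0.0
    for ev in events:
        if ev.kind != "exercise":
            continue
        e = (t64 - np.datetime64(ev.t, "s")) / np.timedelta64(60, "s")
        if 0 <= e <= window:
            best = max(best, float(ev.intensity))
    return best


def feature_matrix(
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    params: PhysioParams,
    end_indices: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Feature rows for many window-end indices at once (training path).

    Callers are responsible for passing end indices whose history windows are
    gap-free (as produced by :func:`cgmforecast.core.sliding_windows`).
    """
    end_indices = np.asarray(end_indices, dtype=int)
    n_lags = config.n_lags(series.step)
    if len(end_indices) and end_indices.min() < n_lags - 1:
        raise FeatureUnavailableError("history window extends before the series start")
    # lag columns: lag_0 = value at end, lag_k = value k steps earlier
    lag_cols = [series.values[end_indices - k] for k in range(n_lags)]
    lags = np.column_stack(lag_cols)
    diffs = lags[:, :-1] - lags[:, 1:]  # per-step first differences, newest first
    iob, cob, iob_rate, cob_rate = onboard_arrays(events, series.times, params)
    ts = pd.DatetimeIndex(series.times[end_indices])
    minute_of_day = ts.hour.to_numpy() * 60 + ts.minute.to_numpy()
    angle = 2 * np.pi * minute_of_day / 1440.0
    activity = np.array(
        [_activity_summary(events, series.times[i], config.activity_window) for i in end_indices]
    )
    return np.column_stack(
        [
            lags,
            diffs,
            iob[end_indices],
            cob[end_indices],
            iob_rate[end_indices],
            cob_rate[end_indices],
            np.sin(angle),
            np.cos(angle),
            ts.dayofweek.to_numpy().astype(float),
            activity,
        ]
    )


def build_features(
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    profile: PatientProfile,
    params: PhysioParams,
    t,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the model input vector for a prediction anchored at ``t``.

    Requires a gap-free history window of ``config.history`` minutes ending
    exactly at a sample at ``t``; otherwise raises
    :class:`FeatureUnavailableError`.
    """
    i = series.index_of(t)
    if i < 0:
        raise FeatureUnavailableError(f"no sample at {t}")
    seg = None
    for i0, i1 in gap_free_segments(series, config.max_gap):
        if i0 <= i <= i1:
            seg = (i0, i1)
            break
    assert seg is not None
    span = (series.times[i] - series.times[seg[0]]) / np.timedelta64(60, "s")
    if span < config.history - JITTER_TOL:
        raise FeatureUnavailableError("history window crosses a data gap")
    row = feature_matrix(series, events, params, np.array([i]), config)[0]
    return FeatureVector(values=row, names=config.names(series.step))
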