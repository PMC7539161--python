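"""Core CGM data containers: glucose series, event records, patient profiles.

All glucose values are mg/dL throughout the package; mmol/L conversion
(x 18.016) belongs at the I/O boundary only.  Timestamps are naive local
time at minute resolution — time-of-day features need wall-clock time.
Real sensors drift, so any spacing comparison uses a +/-1 minute jitter
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: CGM sensor reporting limits, mg/dL.  Standard Dexcom/Medtronic clamp.
SENSOR_MIN = 40.0
SENSOR_MAX = 400.0

#: Tolerance (minutes) when judging sample spacing against the nominal step.
JITTER_TOL = 1.0

#: Default gap threshold: three missed 5-minute points.
DEFAULT_MAX_GAP = 15.0

EVENT_KINDS = ("meal", "bolus", "basal", "exercise", "session")

MMOL_PER_L_TO_MGDL = 18.016


class EmptySeriesError(ValueError):
    """Raised when an operation requires at least one glucose sample."""


class ConfigError(ValueError):
    """Raised for invalid configuration values (e.g. max_gap < step)."""


@dataclass(frozen=True)
class GlucoseSample:
    """A single CGM reading: naive local timestamp and glucose in mg/dL."""

    t: pd.Timestamp
    value: float


@dataclass
class EventRecord:
    """A timestamped patient event: meal, bolus, basal, exercise or app session.

    The payload fields are kind-specific; irrelevant fields stay at their
    zero defaults.  ``insulin_units`` holds units for a bolus and a rate in
    U/h for a basal record (basal is background insulin and does not enter
    insulin-on-board).
    """

    t: pd.Timestamp
    kind: str
    carbs: float = 0.0
    protein: float = 0.0
    fat: float = 0.0
    glycemic_index: float = 0.0
    insulin_units: float = 0.0
    insulin_type: str = ""
    intensity: int = 0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        self.t = pd.Timestamp(self.t)
        for name in ("carbs", "protein", "fat", "glycemic_index", "insulin_units", "duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.kind} event at {self.t}: {name} must be non-negative")


@dataclass
class PatientProfile:
    """Static per-patient therapy parameters supplied at sign-up."""

    patient_id: str
    icr: float = 10.0          # insulin-to-carbohydrate ratio, g/U
    cf: float = 40.0           # correction factor, mg/dL per U
    target_low: float = 70.0   # mg/dL
    target_high: float = 180.0
    cgm_step: float = 5.0      # minutes

    def __post_init__(self) -> None:
        if self.icr <= 0 or self.cf <= 0:
            raise ConfigError("icr and cf must be positive")
        if not self.target_low < self.target_high:
            raise ConfigError("target_low must be below target_high")


@dataclass
class GlucoseSeries:
    """An ordered CGM series stored as parallel numpy arrays.

    ``times`` is datetime64[s] (minute resolution suffices), ``values`` is
    float64 mg/dL, ``step`` the nominal sampling interval in minutes.
    """

    times: np.ndarray
    values: np.ndarray
    step: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.step <= 0:
            raise ConfigError("step must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def samples(self) -> list[GlucoseSample]:
        return [GlucoseSample(pd.Timestamp(t), float(v)) for t, v in zip(self.times, self.values)]

    @classmethod
    def from_samples(cls, samples: Sequence[GlucoseSample], step: float = 5.0) -> "GlucoseSeries":
        return cls(
            times=np.array([np.datetime64(s.t, "s") for s in samples]),
            values=np.array([s.value for s in samples], dtype=float),
            step=step,
        )

    def minutes(self, origin: np.datetime64 | None = None) -> np.ndarray:
        """Sample times as float minutes relative to ``origin`` (default: first sample)."""
        if len(self) == 0:
            return np.empty(0)
        if origin is None:
            origin = self.times[0]
        return (self.times - np.datetime64(origin, "s")) / np.timedelta64(60, "s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": pd.DatetimeIndex(self.times), "glucose_mgdl": self.values})

    def slice(self, i0: int, i1: int) -> "GlucoseSeries":
        """Sub-series over the half-open index range [i0, i1)."""
        return GlucoseSeries(self.times[i0:i1], self.values[i0:i1], self.step)

    def index_of(self, t, tol: float = JITTER_TOL) -> int:
        """Index of the sample at time ``t`` (within ``tol`` minutes), or -1."""
        t64 = np.datetime64(pd.Timestamp(t), "s")
        i = int(np.searchsorted(self.times, t64))
        for j in (i - 1, i):
            if 0 <= j < len(self):
                if abs((self.times[j] - t64) / np.timedelta64(60, "s")) <= tol:
                    return j
        return -1


def validate_and_clamp(series: GlucoseSeries) -> GlucoseSeries:
    """Sort, deduplicate (keep-last) and clamp a raw series to sensor limits.

    Idempotent.  Raises :class:`EmptySeriesError` on an empty series.
    """
    if len(series) == 0:
        raise EmptySeriesError("glucose series is empty")
    order = np.argsort(series.times, kind="stable")
    t = series.times[order]
    v = series.values[order]
    # keep-last on duplicate timestamps: later upload supersedes
    keep = np.ones(len(t), dtype=bool)
    keep[:-1] = t[1:] != t[:-1]
    t, v = t[keep], v[keep]
    v = np.clip(v, SENSOR_MIN, SENSOR_MAX)
    return GlucoseSeries(t, v, series.step)


def detect_gaps(series: GlucoseSeries, max_gap: float = DEFAULT_MAX_GAP) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Maximal intervals between consecutive samples spaced more than ``max_gap``.

    Spacing is judged with the +/-1 min jitter tolerance, so a nominal
    15-minute threshold does not fire on 15.5-minute drifted spacing.
    """
    if max_gap < series.step:
        raise ConfigError(f"max_gap ({max_gap}) must be >= step ({series.step})")
    if len(series) < 2:
        return []
    dt = np.diff(series.times) / np.timedelta64(60, "s")
    idx = np.nonzero(dt > max_gap + JITTER_TOL)[0]
    return [(pd.Timestamp(series.times[i]), pd.Timestamp(series.times[i + 1])) for i in idx]


def gap_free_segments(series: GlucoseSeries, max_gap: float = DEFAULT_MAX_GAP) -> list[tuple[int, int]]:
    """Inclusive index ranges (i0, i1) of maximal gap-free runs."""
    if len(series) == 0:
        return []
    if len(series) == 1:
        return [(0, 0)]
    dt = np.diff(series.times) / np.timedelta64(60, "s")
    breaks = np.nonzero(dt > max_gap + JITTER_TOL)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(series) - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


class Window(NamedTuple):
    """A supervised (history, target) pair emitted by :func:`sliding_windows`.

    ``start``/``end`` delimit the inclusive history index range ending at the
    anchor sample; ``target`` indexes the sample exactly ``horizon`` minutes
    after the anchor.
    """

    start: int
    end: int
    target: int


def sliding_windows(
    series: GlucoseSeries,
    history: float,
    horizon: float,
    max_gap: float = DEFAULT_MAX_GAP,
) -> Iterator[Window]:
    """Enumerate supervised windows fully inside gap-free segments.

    A window is admissible when a full ``history`` minutes of samples precede
    its end within one gap-free segment and a sample exists exactly
    ``horizon`` minutes after the end (jitter-tolerant), in the same segment.
    """
    for m, name in ((history, "history"), (horizon, "horizon")):
        if abs(m / series.step - round(m / series.step)) > 1e-9 or m <= 0:
            raise ConfigError(f"{name} must be a positive multiple of the step")
    mins = series.minutes()
    for i0, i1 in gap_free_segments(series, max_gap):
        seg = mins[i0 : i1 + 1]
        for e_rel in range(len(seg)):
            if seg[e_rel] - seg[0] < history - JITTER_TOL:
                continue
            target_min = seg[e_rel] + horizon
            t_rel = int(np.searchsorted(seg, target_min - JITTER_TOL))
            if t_rel >= len(seg) or abs(seg[t_rel] - target_min) > JITTER_TOL:
                continue
            s_rel = int(np.searchsorted(seg, seg[e_rel] - history - JITTER_TOL))
            yield Window(i0 + s_rel, i0 + e_rel, i0 + t_rel)
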