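"""Glucose-control metrics and the usage-stratified day-level comparison.

Metrics per glucose series: mean, SD, time-in-range (70-180 mg/dL,
inclusive), the glucose management indicator GMI(%) = 3.31 + 0.02392 x mean
glucose (mg/dL), and the Kovatchev blood-glucose risk indices.  The risk
transform f(bg) = 1.509 * ((ln bg)^1.084 - 5.381) symmetrises the glucose
scale around ~112.5 mg/dL; LBGI is the mean of 10*f^2 over readings with
f < 0, HBGI the mean over readings with f > 0.

The stratified analysis bins patient-days by the number of daily app
sessions (0, 1-5, 6-10, >10), computes day-level metric means per bin, and
reports one-sided Welch t-test p-values of each bin against the 0-session
bin (P0) and against the adjacent bin with fewer sessions (P_fewer), with a
Bonferroni-corrected per-comparison alpha of .01/36 (6 metrics x 3 non-zero
bins x 2 comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import EmptySeriesError, GlucoseSeries

GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392

RISK_BG_MIN = 20.0
RISK_BG_MAX = 600.0

SESSION_BINS = ("0", "1-5", "6-10", ">10")

#: direction in which each metric is hypothesised to move with more app use
METRIC_DIRECTIONS = {
    "mean_bg": "less",
    "sd_bg": "less",
    "tir": "greater",
    "gmi": "less",
    "hbgi": "less",
    "lbgi": "greater",  # tighter control slightly raises hypoglycemia risk
}

ALPHA = 0.01
N_COMPARISONS = 36


class DomainError(ValueError):
    """Raised for glucose inputs outside a metric's published domain."""


def time_in_range(series: GlucoseSeries, low: float = 70.0, high: float = 180.0) -> float:
    """Percentage of samples with low <= value <= high (inclusive bounds)."""
    if len(series) == 0:
        raise EmptySeriesError("time_in_range requires a non-empty series")
    if not low < high:
        raise ValueError("low must be below high")
    inside = (series.values >= low) & (series.values <= high)
    return 100.0 * float(np.mean(inside))


def gmi(mean_bg: float) -> float:
    """Glucose management indicator (%), rounded to two decimals."""
    if mean_bg <= 0:
        raise DomainError("mean glucose must be positive")
    return round(GMI_INTERCEPT + GMI_SLOPE * mean_bg, 2)


def risk_transform(bg: float) -> tuple[float, float, float]:
    """Kovatchev risk transform: (f, rl, rh) for one reading.

    rl = 10*f^2 when f < 0 (hypoglycemic side), rh = 10*f^2 when f > 0;
    exactly one of rl, rh is nonzero away from the ~112.5 mg/dL crossing.
    """
    if not RISK_BG_MIN <= bg <= RISK_BG_MAX:
        raise DomainError(f"bg {bg} outside the risk transform domain [{RISK_BG_MIN}, {RISK_BG_MAX}]")
    f = 1.509 * (math.log(bg) ** 1.084 - 5.381)
    risk = 10.0 * f * f
    rl = risk if f < 0 else 0.0
    rh = risk if f > 0 else 0.0
    return f, rl, rh


def _risk_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    if np.any(v < RISK_BG_MIN) or np.any(v > RISK_BG_MAX):
        raise DomainError("glucose values outside the risk transform domain")
    f = 1.509 * (np.log(v) ** 1.084 - 5.381)
    risk = 10.0 * f * f
    return np.where(f < 0, risk, 0.0), np.where(f > 0, risk, 0.0)


def lbgi_hbgi(series: GlucoseSeries) -> tuple[float, float]:
    """(LBGI, HBGI): means of the low/high risk components over the series."""
    if len(series) == 0:
        raise EmptySeriesError("risk indices require a non-empty series")
    rl, rh = _risk_arrays(series.values)
    return float(np.mean(rl)), float(np.mean(rh))


def hbgi_category(hbgi: float) -> str:
    """Published HBGI risk bands: <4.5 low; 4.5-9.0 moderate; >9.0 high."""
    if hbgi < 4.5:
        return "low risk"
    if hbgi <= 9.0:
        return "moderate risk"
    return "high risk"


def lbgi_category(lbgi: float) -> str:
    """Published LBGI bands: <1.1 minimal; 1.1-2.5 low; 2.5-5.0 moderate; >5.0 high."""
    if lbgi < 1.1:
        return "minimal risk"
    if lbgi <= 2.5:
        return "low risk"
    if lbgi <= 5.0:
        return "moderate risk"
    return "high risk"


def bonferroni_alpha(alpha: float = ALPHA, n_comparisons: int = N_COMPARISONS,
                     sig_digits: int = 2) -> float:
    """Corrected per-comparison alpha, truncated to ``sig_digits`` significant digits.

    .01/36 = 0.0002777... reports as .00027 under 2-significant-digit truncation.
    """
    raw = alpha / n_comparisons
    if raw <= 0:
        raise ValueError("alpha must be positive")
    exponent = math.floor(math.log10(raw))
    scale = 10.0 ** (exponent - sig_digits + 1)
    return math.floor(raw / scale) * scale


@dataclass
class MetricsRow:
    """Glucose-control summary of one series (typically one patient-day)."""

    mean_bg: float
    sd_bg: float
    tir: float
    gmi: float
    lbgi: float
    hbgi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_bg": self.mean_bg,
            "sd_bg": self.sd_bg,
            "tir": self.tir,
            "gmi": self.gmi,
            "lbgi": self.lbgi,
            "hbgi": self.hbgi,
        }


METRICS = ("mean_bg", "sd_bg", "tir", "gmi", "lbgi", "hbgi")


def metrics_row(series: GlucoseSeries, low: float = 70.0, high: float = 180.0) -> MetricsRow:
    """All six control metrics for one series."""
    if len(series) == 0:
        raise EmptySeriesError("metrics require a non-empty series")
    mean_bg = float(np.mean(series.values))
    lbgi, hbgi = lbgi_hbgi(series)
    return MetricsRow(
        mean_bg=mean_bg,
        sd_bg=float(np.std(series.values, ddof=1)) if len(series) > 1 else 0.0,
        tir=time_in_range(series, low, high),
        gmi=gmi(mean_bg),
        lbgi=lbgi,
        hbgi=hbgi,
    )


@dataclass
class DayRecord:
    """One patient-day: session count plus that day's glucose series."""

    date: pd.Timestamp
    patient_id: str
    sessions: int
    series: GlucoseSeries

    def __post_init__(self) -> None:
        if self.sessions < 0:
            raise ValueError("sessions must be non-negative")


def session_bin(sessions: int) -> str:
    """Bin a daily session count: 0, 1-5, 6-10, >10 (a partition of the
    non-negative integers)."""
    if sessions < 0:
        raise ValueError("sessions must be non-negative")
    if sessions == 0:
        return "0"
    if sessions <= 5:
        return "1-5"
    if sessions <= 10:
        return "6-10"
    return ">10"


def split_days(series: GlucoseSeries, sessions_by_date: dict, patient_id: str) -> list[DayRecord]:
    """Split a long series into calendar-day records.

    ``sessions_by_date`` maps date -> session count; days with CGM data but
    no entry count as zero sessions (the app records data even when unused).
    """
    if len(series) == 0:
        return []
    frame = series.to_frame()
    out = []
    for date, group in frame.groupby(frame["timestamp"].dt.date):
        day = GlucoseSeries(
            group["timestamp"].to_numpy(), group["glucose_mgdl"].to_numpy(), series.step
        )
        out.append(
            DayRecord(
                date=pd.Timestamp(date),
                patient_id=patient_id,
                sessions=int(sessions_by_date.get(date, sessions_by_date.get(pd.Timestamp(date), 0))),
                series=day,
            )
        )
    return out


def welch_one_sided(group: np.ndarray, baseline: np.ndarray, alternative: str) -> float:
    """One-sided Welch t-test p-value for group vs baseline.

    ``alternative`` is the hypothesised direction of the *group* relative to
    the baseline ('less' or 'greater').  Returns NaN when either side has
    fewer than two observations.
    """
    if len(group) < 2 or len(baseline) < 2:
        return float("nan")
    if np.var(group) == 0.0 and np.var(baseline) == 0.0:
        # degenerate zero-variance limit: t = 0 when the means agree,
        # +/-inf otherwise
        diff = float(np.mean(group) - np.mean(baseline))
        if diff == 0.0:
            return 0.5
        toward = (alternative == "less" and diff < 0) or (alternative == "greater" and diff > 0)
        return 0.0 if toward else 1.0
    res = stats.ttest_ind(group, baseline, equal_var=False, alternative=alternative)
    return float(res.pvalue)


@dataclass
class StratifiedTable:
    """Usage-stratified day-level comparison: the machinery behind a
    sessions-vs-metrics report."""

    group_means: dict[str, MetricsRow]
    group_sizes: dict[str, int]
    p_zero: dict[str, dict[str, float]]    # bin -> metric -> p vs the 0-session bin
    p_fewer: dict[str, dict[str, float]]   # bin -> metric -> p vs adjacent smaller bin
    alpha_corrected: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in SESSION_BINS:
            if b not in self.group_means:
                continue
            row = {"sessions": b, "n_days": self.group_sizes[b]}
            row.update({m: getattr(self.group_means[b], m) for m in METRICS})
            for m in METRICS:
                row[f"p0_{m}"] = self.p_zero.get(b, {}).get(m, float("nan"))
                row[f"pfewer_{m}"] = self.p_fewer.get(b, {}).get(m, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def usage_stratified_table(days: Sequence[DayRecord]) -> StratifiedTable:
    """Bin patient-days by session count and test each metric's improvement.

    Days are the unit of analysis, pooled across patients.  Direction of the
    one-sided tests follows :data:`METRIC_DIRECTIONS`.
    """
    per_day = []
    for d in days:
        if len(d.series) == 0:
            continue
        row = metrics_row(d.series).as_dict()
        row["bin"] = session_bin(d.sessions)
        per_day.append(row)
    if not per_day:
        raise ValueError("no non-empty day records supplied")
    frame = pd.DataFrame(per_day)
    present = [b for b in SESSION_BINS if (frame["bin"] == b).any()]
    if len(present) < 2:
        raise ValueError("stratified comparison needs at least two non-empty session groups")

    values = {b: frame[frame["bin"] == b] for b in present}
    group_means = {
        b: MetricsRow(**{m: float(values[b][m].mean()) for m in METRICS}) for b in present
    }
    group_sizes = {b: int(len(values[b])) for b in present}

    p_zero: dict[str, dict[str, float]] = {}
    p_fewer: dict[str, dict[str, float]] = {}
    for i, b in enumerate(present):
        if b == "0":
            continue
        p_zero[b] = {}
        p_fewer[b] = {}
        for m in METRICS:
            direction = METRIC_DIRECTIONS[m]
            if "0" in values:
                p_zero[b][m] = welch_one_sided(
                    values[b][m].to_numpy(), values["0"][m].to_numpy(), direction
                )
            else:
                p_zero[b][m] = float("nan")
            prev = present[i - 1] if i > 0 else None
            p_fewer[b][m] = (
                welch_one_sided(values[b][m].to_numpy(), values[prev][m].to_numpy(), direction)
                if prev is not None
                else float("nan")
            )
    return StratifiedTable(
        group_means=group_means,
        group_sizes=group_sizes,
        p_zero=p_zero,
        p_fewer=p_fewer,
        alpha_corrected=bonferroni_alpha(),
    )
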