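"""Seeded simulator of free-living CGM traces with meals, boluses, exercise,
sensor noise, data gaps and daily app-session counts.

The dynamics are a transparent linear-response difference model, not a
published ODE physiology: glucose integrates carb absorption (linear over
the carb absorption duration) minus insulin action (linear over the insulin
action duration), a circadian baseline oscillation, a weak homeostatic pull
toward that baseline, and a small integrated process noise; the reported
value adds white sensor noise and clamps to the 40-400 mg/dL sensor range.
This gives the forecaster genuinely learnable structure (announced meals and
boluses act over known horizons) and the metrics realistic distributions,
while every draw is reproducible from the seed.

Random streams for events, process noise, sensor noise, gaps and sessions
are spawned separately from the seed, so deleting an event and re-running
with the same seed yields a paired counterfactual trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EventRecord, GlucoseSeries, PatientProfile, SENSOR_MAX, SENSOR_MIN


@dataclass
class SimParams:
    """Simulator settings; the defaults describe a typical type 1 adult on
    rapid-acting insulin with a 5-minute sensor."""

    basal_glucose: float = 110.0        # mg/dL
    circadian_amplitude: float = 15.0   # mg/dL
    meal_rate: float = 3.0              # meals/day
    carb_range: tuple[float, float] = (20.0, 80.0)  # g
    bolus_timing_jitter: float = 10.0   # SD of bolus delay vs meal, minutes
    missed_bolus_prob: float = 0.1
    insulin_sensitivity: float = 40.0   # mg/dL per U (the correction factor)
    carb_sensitivity: float = 3.5       # mg/dL per g
    icr: float = 10.0                   # g/U; bolus units = carbs/icr
    dia: float = 240.0                  # minutes
    cad: float = 180.0                  # minutes
    mean_reversion: float = 0.005       # per minute, pull toward baseline
    noise_sd: float = 5.0               # mg/dL white sensor noise
    process_noise_sd: float = 1.5       # mg/dL per step, integrated
    exercise_rate: float = 0.5          # bouts/day
    exercise_drop: float = 0.3          # mg/dL per min per intensity level
    gap_rate: float = 0.5               # gaps/day
    gap_minutes: tuple[float, float] = (20.0, 120.0)
    session_mean: float = 5.0           # mean daily app sessions
    step: float = 5.0                   # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("meal_rate", "exercise_rate", "gap_rate", "noise_sd", "process_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimDetails:
    """Ground-truth bookkeeping returned alongside the observable data."""

    true_series: GlucoseSeries
    gap_intervals: list[tuple[pd.Timestamp, pd.Timestamp]]
    session_counts: dict = field(default_factory=dict)  # date -> sessions
    regime: np.ndarray = None  # per-sample sign of the net event-driven drive:
                               # +1 rising (carbs dominate), -1 falling, 0 quiescent


@dataclass
class PatientDataset:
    """One simulated patient: observable series/events/profile plus details."""

    series: GlucoseSeries
    events: list[EventRecord]
    profile: PatientProfile
    details: SimDetails


START = pd.Timestamp("2019-03-01 00:00:00")


def _generate_events(params: SimParams, days: int, rng: np.random.Generator) -> list[EventRecord]:
    events: list[EventRecord] = []
    for day in range(days):
        day_start = START + pd.Timedelta(days=day)
        n_meals = rng.poisson(params.meal_rate)
        meal_minutes = np.sort(rng.uniform(6.5 * 60, 21.5 * 60, size=n_meals))
        for m in meal_minutes:
            carbs = rng.uniform(*params.carb_range)
            t_meal = day_start + pd.Timedelta(minutes=float(m))
            events.append(EventRecord(t=t_meal, kind="meal", carbs=round(carbs, 1),
                                      protein=round(carbs * 0.4, 1), fat=round(carbs * 0.3, 1),
                                      glycemic_index=round(rng.uniform(40, 80))))
            if rng.uniform() >= params.missed_bolus_prob:
                delay = rng.normal(0.0, params.bolus_timing_jitter)
                t_bolus = t_meal + pd.Timedelta(minutes=float(delay))
                units = round(carbs / params.icr, 1)
                events.append(EventRecord(t=t_bolus, kind="bolus",
                                          insulin_units=units, insulin_type="rapid"))
        n_ex = rng.poisson(params.exercise_rate)
        for _ in range(n_ex):
            t_ex = day_start + pd.Timedelta(minutes=float(rng.uniform(7 * 60, 21 * 60)))
            events.append(EventRecord(t=t_ex, kind="exercise",
                                      intensity=int(rng.integers(1, 4)),
                                      duration=float(rng.integers(30, 61))))
    events.sort(key=lambda e: e.t)
    return events


def _circadian(minute_of_day: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.sin(2 * np.pi * (minute_of_day / 60.0 - 8.0) / 24.0)


def simulate_patient(
    params: SimParams,
    days: int,
    events: Sequence[EventRecord] | None = None,
    patient_id: str = "sim-001",
) -> tuple[GlucoseSeries, list[EventRecord], PatientProfile, SimDetails]:
    """Simulate ``days`` of 5-minute CGM data for one patient.

    Pass ``events`` to override the generated event log (e.g. with one meal
    deleted) while keeping every noise draw identical — the event stream and
    the noise streams come from independently spawned child generators of the
    same seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    root = np.random.default_rng(params.seed)
    event_rng, noise_rng, gap_rng, session_rng = root.spawn(4)

    if events is None:
        events = _generate_events(params, days, event_rng)
    else:
        _ = _generate_events(params, days, event_rng)  # keep stream alignment
        events = list(events)

    n = int(days * 24 * 60 / params.step)
    times = np.datetime64(START, "s") + (
        np.arange(n) * np.timedelta64(int(params.step * 60), "s")
    )
    minute_of_day = ((times - np.datetime64(START, "s")) / np.timedelta64(60, "s")) % 1440.0
    circ = _circadian(minute_of_day, params.circadian_amplitude)
    baseline = params.basal_glucose + circ

    # per-step event-driven rates (linear kinetics, vectorised over events)
    carb_rate = np.zeros(n)
    insulin_rate = np.zeros(n)
    exercise = np.zeros(n)
    t_min = (times - np.datetime64(START, "s")) / np.timedelta64(60, "s")
    for ev in events:
        e = (np.datetime64(ev.t, "s") - np.datetime64(START, "s")) / np.timedelta64(60, "s")
        if ev.kind == "meal":
            active = (t_min >= e) & (t_min < e + params.cad)
            carb_rate[active] += ev.carbs / params.cad
        elif ev.kind == "bolus":
            active = (t_min >= e) & (t_min < e + params.dia)
            insulin_rate[active] += ev.insulin_units / params.dia
        elif ev.kind == "exercise":
            active = (t_min >= e) & (t_min < e + ev.duration)
            exercise[active] += params.exercise_drop * ev.intensity

    net_drive = params.carb_sensitivity * carb_rate - params.insulin_sensitivity * insulin_rate - exercise
    regime = np.where(net_drive > 0.1, 1.0, np.where(net_drive < -0.1, -1.0, 0.0))

    proc_noise = noise_rng.normal(0.0, params.process_noise_sd, size=n)
    sensor_noise = noise_rng.normal(0.0, params.noise_sd, size=n)

    g = np.empty(n)
    g[0] = baseline[0]
    dt = params.step
    for i in range(1, n):
        drift = circ[i] - circ[i - 1]
        dg = (
            params.carb_sensitivity * carb_rate[i - 1] * dt
            - params.insulin_sensitivity * insulin_rate[i - 1] * dt
            - exercise[i - 1] * dt
            + drift
            + params.mean_reversion * (baseline[i - 1] - g[i - 1]) * dt
            + proc_noise[i]
        )
        g[i] = np.clip(g[i - 1] + dg, SENSOR_MIN, SENSOR_MAX)

    measured = np.clip(g + sensor_noise, SENSOR_MIN, SENSOR_MAX)
    true_series = GlucoseSeries(times.copy(), g, params.step)

    # sensor dropouts
    n_gaps = gap_rng.poisson(params.gap_rate * days)
    gap_starts = np.sort(gap_rng.uniform(0, days * 24 * 60, size=n_gaps))
    gap_lengths = gap_rng.uniform(*params.gap_minutes, size=n_gaps)
    keep = np.ones(n, dtype=bool)
    gap_intervals = []
    for s, L in zip(gap_starts, gap_lengths):
        dropped = (t_min > s) & (t_min < s + L)
        if dropped.any():
            keep &= ~dropped
            gap_intervals.append(
                (START + pd.Timedelta(minutes=float(s)), START + pd.Timedelta(minutes=float(s + L)))
            )

    session_counts = {}
    # negative-binomial-ish daily session counts spanning all four usage bins
    p = 2.0 / (2.0 + params.session_mean)
    draws = session_rng.negative_binomial(2, p, size=days)
    for day in range(days):
        session_counts[(START + pd.Timedelta(days=day)).date()] = int(draws[day])

    series = GlucoseSeries(times[keep], measured[keep], params.step)
    profile = PatientProfile(
        patient_id=patient_id,
        icr=params.icr,
        cf=params.insulin_sensitivity if params.insulin_sensitivity > 0 else 40.0,
        cgm_step=params.step,
    )
    details = SimDetails(
        true_series=true_series,
        gap_intervals=gap_intervals,
        session_counts=session_counts,
        regime=regime[keep],
    )
    return series, list(events), profile, details


def generate_cohort(
    template: SimParams, n_patients: int, days: int, master_seed: int
) -> list[PatientDataset]:
    """Simulate ``n_patients`` independent patients with jittered parameters.

    Per-patient seeds derive deterministically from ``master_seed``; the
    parameter jitter (basal glucose, sensitivities, meal habits) makes the
    cohort heterogeneous without leaving realistic ranges.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_patients) % (2**31)
    jitter_rng = np.random.default_rng(np.random.SeedSequence(master_seed).generate_state(1)[0] % (2**31))
    cohort = []
    for k in range(n_patients):
        params = replace(
            template,
            basal_glucose=template.basal_glucose + jitter_rng.uniform(-15, 25),
            insulin_sensitivity=template.insulin_sensitivity * jitter_rng.uniform(0.8, 1.2),
            carb_sensitivity=template.carb_sensitivity * jitter_rng.uniform(0.8, 1.2),
            meal_rate=template.meal_rate * jitter_rng.uniform(0.8, 1.2),
            session_mean=max(0.5, template.session_mean + jitter_rng.uniform(-3, 3)),
            seed=int(seeds[k]),
        )
        series, events, profile, details = simulate_patient(
            params, days, patient_id=f"sim-{k:03d}"
        )
        cohort.append(PatientDataset(series=series, events=events, profile=profile, details=details))
    return cohort
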