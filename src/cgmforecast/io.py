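"""Readers and writers: CSV series/event dialects, Ohio-style per-patient
XML, and the run configuration file.

CSV series dialect: header ``timestamp,glucose_mgdl``, ISO-8601 naive local
timestamps, glucose to 0.1 mg/dL.  Events CSV: ``timestamp,kind,carbs_g,
protein_g,fat_g,gi,insulin_units,insulin_type,intensity,duration_min`` with
empty fields allowed.  Unknown extra columns are accepted with a warning
(tolerant reader).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EventRecord, GlucoseSeries, PatientProfile
from .forecast import HORIZONS, TrainConfig

log = logging.getLogger("cgmforecast")

SERIES_COLUMNS = ["timestamp", "glucose_mgdl"]
EVENT_COLUMNS = [
    "timestamp", "kind", "carbs_g", "protein_g", "fat_g", "gi",
    "insulin_units", "insulin_type", "intensity", "duration_min",
]

#: Ohio-style XML timestamp format (dialect defined by this repo's fixtures).
OHIO_TS_FORMAT = "%d-%m-%Y %H:%M:%S"


class SchemaError(ValueError):
    """Raised when a CSV file does not match the expected column schema."""


def read_series_csv(path) -> GlucoseSeries:
    """Read a glucose series from the ``timestamp,glucose_mgdl`` dialect."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file; expected columns {SERIES_COLUMNS}")
    missing = [c for c in SERIES_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected {SERIES_COLUMNS}")
    extra = [c for c in frame.columns if c not in SERIES_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    times = pd.to_datetime(frame["timestamp"]).to_numpy().astype("datetime64[s]")
    return GlucoseSeries(times, frame["glucose_mgdl"].to_numpy(dtype=float))


def write_series_csv(series: GlucoseSeries, path) -> None:
    frame = series.to_frame()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    frame["glucose_mgdl"] = frame["glucose_mgdl"].round(1)
    frame.to_csv(path, index=False)


_EVENT_FIELD_MAP = {
    "carbs_g": "carbs", "protein_g": "protein", "fat_g": "fat", "gi": "glycemic_index",
    "insulin_units": "insulin_units", "insulin_type": "insulin_type",
    "intensity": "intensity", "duration_min": "duration",
}


def read_events_csv(path) -> list[EventRecord]:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file; expected columns {EVENT_COLUMNS}")
    missing = [c for c in ("timestamp", "kind") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected {EVENT_COLUMNS}")
    events = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col, attr in _EVENT_FIELD_MAP.items():
            if col in frame.columns and pd.notna(row[col]) and row[col] != "":
                if attr == "insulin_type":
                    kwargs[attr] = str(row[col])
                elif attr == "intensity":
                    kwargs[attr] = int(row[col])
                else:
                    kwargs[attr] = float(row[col])
        events.append(EventRecord(t=pd.Timestamp(row["timestamp"]), kind=str(row["kind"]), **kwargs))
    events.sort(key=lambda e: e.t)
    return events


def write_events_csv(events, path) -> None:
    rows = []
    for ev in events:
        rows.append({
            "timestamp": pd.Timestamp(ev.t).strftime("%Y-%m-%dT%H:%M"),
            "kind": ev.kind, "carbs_g": ev.carbs or "", "protein_g": ev.protein or "",
            "fat_g": ev.fat or "", "gi": ev.glycemic_index or "",
            "insulin_units": ev.insulin_units or "", "insulin_type": ev.insulin_type or "",
            "intensity": ev.intensity or "", "duration_min": ev.duration or "",
        })
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_profile(profile: PatientProfile, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(profile)))


def read_profile(path) -> PatientProfile:
    return PatientProfile(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Ohio-style per-patient XML


def _parse_ohio_ts(value: str, stream: str) -> pd.Timestamp:
    try:
        return pd.Timestamp(pd.to_datetime(value, format=OHIO_TS_FORMAT))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed timestamp {value!r} in stream '{stream}'") from exc


def read_ohio_xml(path) -> tuple[GlucoseSeries, list[EventRecord], dict]:
    """Read one Ohio-style per-patient XML file.

    Supported streams: glucose_level (ts/value), meal (ts/carbs), bolus
    (ts_begin/dose), basal (ts/value, U/h piecewise-constant rate), exercise
    (ts/intensity/duration).  Out-of-order timestamps are sorted with a
    logged warning.  Glucose is mg/dL.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    root = ET.parse(path).getroot()
    meta = {"patient_id": root.get("id", path.stem), "insulin_type": root.get("insulin_type", "")}

    glucose = root.find("glucose_level")
    t_list, v_list = [], []
    if glucose is not None:
        for ev in glucose.findall("event"):
            ts = ev.get("ts")
            value = ev.get("value")
            if ts is None or value is None:
                raise ValueError("malformed event in stream 'glucose_level': missing ts/value")
            t_list.append(_parse_ohio_ts(ts, "glucose_level"))
            try:
                v_list.append(float(value))
            except ValueError as exc:
                raise ValueError(f"malformed value {value!r} in stream 'glucose_level'") from exc
    if t_list and any(t_list[i] > t_list[i + 1] for i in range(len(t_list) - 1)):
        log.warning("%s: glucose_level timestamps out of order; sorting", path.name)
    order = np.argsort(np.array([np.datetime64(t, "s") for t in t_list])) if t_list else []
    times = np.array([np.datetime64(t_list[i], "s") for i in order])
    values = np.array([v_list[i] for i in order], dtype=float)
    series = GlucoseSeries(times, values) if len(times) else GlucoseSeries(times, values)

    events: list[EventRecord] = []
    meal = root.find("meal")
    if meal is not None:
        for ev in meal.findall("event"):
            events.append(EventRecord(
                t=_parse_ohio_ts(ev.get("ts"), "meal"), kind="meal",
                carbs=float(ev.get("carbs", 0) or 0),
            ))
    bolus = root.find("bolus")
    if bolus is not None:
        for ev in bolus.findall("event"):
            ts = ev.get("ts_begin") or ev.get("ts")
            events.append(EventRecord(
                t=_parse_ohio_ts(ts, "bolus"), kind="bolus",
                insulin_units=float(ev.get("dose", 0) or 0), insulin_type="rapid",
            ))
    basal = root.find("basal")
    if basal is not None:
        basal_events = []
        for ev in basal.findall("event"):
            basal_events.append((_parse_ohio_ts(ev.get("ts"), "basal"), float(ev.get("value", 0) or 0)))
        basal_events.sort(key=lambda x: x[0])
        # piecewise-constant rate: each record lasts until the next one
        for k, (t, rate) in enumerate(basal_events):
            if k + 1 < len(basal_events):
                dur = (basal_events[k + 1][0] - t).total_seconds() / 60.0
            else:
                dur = 0.0
            events.append(EventRecord(t=t, kind="basal", insulin_units=rate,
                                      insulin_type="long", duration=dur))
    exercise = root.find("exercise")
    if exercise is not None:
        for ev in exercise.findall("event"):
            events.append(EventRecord(
                t=_parse_ohio_ts(ev.get("ts"), "exercise"), kind="exercise",
                intensity=int(float(ev.get("intensity", 0) or 0)),
                duration=float(ev.get("duration", 0) or 0),
            ))
    events.sort(key=lambda e: e.t)
    return series, events, meta


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything a run needs to be reproducible: feature/model settings,
    adjustment weights, target range, gap threshold and the seed."""

    seed: int = 0
    history: float = 60.0
    max_gap: float = 15.0
    horizons: tuple = HORIZONS
    k_states: int = 5
    min_state_n: int = 200
    max_train_pairs: int = 8000
    tree_depth: int = 4
    boosting_rounds: int = 200
    svr_c: float = 10.0
    svr_epsilon: float = 2.0
    adjustment_enabled: bool = True
    weight_linear_15: float = 0.25
    weight_linear_60: float = 0.60
    target_low: float = 70.0
    target_high: float = 180.0

    def __post_init__(self) -> None:
        if tuple(self.horizons) != HORIZONS:
            raise ValueError(f"horizons are fixed to {HORIZONS}")

    def train_config(self) -> TrainConfig:
        from .physio import FeatureConfig

        return TrainConfig(
            feature=FeatureConfig(history=self.history, max_gap=self.max_gap),
            min_state_n=self.min_state_n,
            max_train_pairs=self.max_train_pairs,
            tree_depth=self.tree_depth,
            boosting_rounds=self.boosting_rounds,
            svr_c=self.svr_c,
            svr_epsilon=self.svr_epsilon,
        )

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["horizons"] = list(self.horizons)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["horizons"] = tuple(data.get("horizons", HORIZONS))
        return cls(**data)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["horizons"] = list(self.horizons)
        return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:12]
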