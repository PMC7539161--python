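"""Shared fixtures: constructed series helpers and session-scoped simulated
patients/bundles reused across the model tests (training is the expensive
step, so it happens once per session)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cgmforecast.core import GlucoseSeries, validate_and_clamp
from cgmforecast.forecast import TrainConfig, train_bundle
from cgmforecast.simulate import SimParams, simulate_patient

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

T0 = pd.Timestamp("2019-06-01 00:00:00")


def make_series(values, start=T0, step=5.0) -> GlucoseSeries:
    """Regular series from a value list, 5-minute spacing by default."""
    values = np.asarray(values, dtype=float)
    times = np.datetime64(start, "s") + np.arange(len(values)) * np.timedelta64(
        int(step * 60), "s"
    )
    return GlucoseSeries(times, values, step)


@pytest.fixture(scope="session")
def patient60():
    """60 simulated days of one patient under the default study conditions."""
    series, events, profile, details = simulate_patient(SimParams(seed=11), 60)
    return validate_and_clamp(series), events, profile, details


@pytest.fixture(scope="session")
def split60(patient60):
    """(train_series first 45 days, full series, holdout boundary timestamp)."""
    series, events, profile, details = patient60
    boundary = np.datetime64(pd.Timestamp("2019-03-01") + pd.Timedelta(days=45), "s")
    n_train = int(np.searchsorted(series.times, boundary))
    return series.slice(0, n_train), series, boundary


@pytest.fixture(scope="session")
def bundle60(patient60, split60):
    """Bundle trained on the first 45 days of the 60-day patient."""
    _, events, profile, _ = patient60
    train_series, _, _ = split60
    return train_bundle(train_series, events, profile, seed=3)


@pytest.fixture(scope="session")
def patient8():
    """A small 8-day patient for fast training tests."""
    series, events, profile, details = simulate_patient(SimParams(seed=21), 8)
    return validate_and_clamp(series), events, profile, details


@pytest.fixture(scope="session")
def bundle8(patient8):
    series, events, profile, _ = patient8
    return train_bundle(series, events, profile, seed=3)
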