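"""On-board kinetics, the sign-up fallback estimate, parameter fitting and
feature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cgmforecast.core import EventRecord, PatientProfile
from cgmforecast.physio import (
    FeatureConfig,
    FeatureUnavailableError,
    PhysioParams,
    build_features,
    estimate_cob,
    estimate_iob,
    fit_physio_params,
    linear_rate,
    linear_remaining,
    simple_onboard_estimate,
)
from cgmforecast.simulate import SimParams, simulate_patient
from cgmforecast.core import validate_and_clamp

from conftest import T0, make_series


def bolus(minutes_before, units, t0=T0):
    return EventRecord(t=t0 - pd.Timedelta(minutes=minutes_before), kind="bolus", insulin_units=units)


def meal(minutes_before, carbs, t0=T0):
    return EventRecord(t=t0 - pd.Timedelta(minutes=minutes_before), kind="meal", carbs=carbs)


class TestOnBoard:
    def test_no_events_zero(self):
        assert estimate_iob([], T0, PhysioParams()).iob == 0.0
        assert estimate_cob([], T0, PhysioParams()).cob == 0.0

    def test_linear_decay_midpoint(self):
        state = estimate_iob([bolus(120, 5.0)], T0, PhysioParams(dia=240))
        assert state.iob == pytest.approx(2.5)
        assert state.iob_rate == pytest.approx(5.0 / 240)

    def test_two_boluses_now_sum(self):
        state = estimate_iob([bolus(0, 3.0), bolus(0, 2.0)], T0, PhysioParams(dia=240))
        assert state.iob == pytest.approx(5.0)

    def test_cob_midpoint_and_boundary(self):
        p = PhysioParams(cad=180)
        assert estimate_cob([meal(90, 60.0)], T0, p).cob == pytest.approx(30.0)
        assert estimate_cob([meal(180, 60.0)], T0, p).cob == 0.0

    def test_basal_excluded_from_iob(self):
        ev = EventRecord(t=T0 - pd.Timedelta(minutes=30), kind="basal", insulin_units=1.2)
        assert estimate_iob([ev], T0, PhysioParams()).iob == 0.0

    @given(st.floats(min_value=0, max_value=500))
    def test_remaining_non_increasing_and_zero_at_duration(self, elapsed):
        dur = 240.0
        r = linear_remaining(np.array([elapsed, elapsed + 1]), dur)
        assert r[0] >= r[1]
        assert linear_remaining(np.array([dur]), dur)[0] == 0.0

    def test_rate_integral_conserves_dose(self):
        # left-Riemann integral of the utilisation rate over [0, dia) = dose
        dur, dose = 240.0, 7.0
        grid = np.arange(0, dur, 1.0)
        total = np.sum(dose * linear_rate(grid, dur) * 1.0)
        assert total == pytest.approx(dose, rel=1e-9)


class TestSimpleOnboard:
    profile = PatientProfile(patient_id="p", icr=10, cf=50)

    def test_bolus_fully_expressed(self):
        s = make_series([300.0, 100.0], start=T0)
        ev = [EventRecord(t=T0, kind="bolus", insulin_units=4.0)]
        state = simple_onboard_estimate(ev, s, self.profile)
        assert state.iob == 0.0

    def test_bolus_half_expressed(self):
        s = make_series([300.0, 200.0], start=T0)
        ev = [EventRecord(t=T0, kind="bolus", insulin_units=4.0)]
        state = simple_onboard_estimate(ev, s, self.profile)
        assert state.iob == pytest.approx(2.0)

    def test_meal_not_yet_expressed(self):
        s = make_series([120.0, 120.0], start=T0)
        ev = [EventRecord(t=T0, kind="meal", carbs=30.0)]
        state = simple_onboard_estimate(ev, s, self.profile)
        assert state.cob == pytest.approx(30.0)

    @given(
        st.floats(min_value=-300, max_value=300),
        st.floats(min_value=0.5, max_value=10),
    )
    def test_bounded_by_dose_and_zero(self, delta, units):
        s = make_series([200.0, 200.0 + max(min(delta, 200), -160)], start=T0)
        s.values[:] = np.clip(s.values, 40, 400)
        ev = [EventRecord(t=T0, kind="bolus", insulin_units=units)]
        state = simple_onboard_estimate(ev, s, self.profile)
        assert 0.0 <= state.iob <= units


class TestFitPhysioParams:
    def test_too_few_events_falls_back(self):
        s = make_series([120.0] * 300)
        p = fit_physio_params(s, [meal(10, 30.0)], PatientProfile(patient_id="p"))
        assert not p.personalized
        assert p.dia == 240 and p.cad == 180

    def test_recovers_simulated_kinetics(self):
        series, events, profile, _ = simulate_patient(SimParams(seed=5, dia=180.0, cad=120.0), 20)
        p = fit_physio_params(validate_and_clamp(series), events, profile)
        assert p.personalized
        assert abs(p.dia - 180.0) <= 30.0
        assert abs(p.cad - 120.0) <= 30.0


class TestBuildFeatures:
    params = PhysioParams()
    profile = PatientProfile(patient_id="p")

    def test_layout_has_31_values(self):
        s = make_series([120.0] * 20)
        fv = build_features(s, [], self.profile, self.params, pd.Timestamp(s.times[-1]))
        assert len(fv.values) == 31
        assert len(fv.names) == 31

    def test_constant_series_zero_differences(self):
        s = make_series([120.0] * 20)
        fv = build_features(s, [], self.profile, self.params, pd.Timestamp(s.times[-1]))
        diffs = [v for n, v in zip(fv.names, fv.values) if n.startswith("diff_")]
        assert all(d == 0.0 for d in diffs)

    def test_midnight_clock_encoding(self):
        start = pd.Timestamp("2019-06-01 22:00:00")
        s = make_series([120.0] * 25, start=start)  # ends exactly at midnight
        fv = build_features(s, [], self.profile, self.params, pd.Timestamp(s.times[-1]))
        by_name = dict(zip(fv.names, fv.values))
        assert by_name["tod_sin"] == pytest.approx(0.0, abs=1e-12)
        assert by_name["tod_cos"] == pytest.approx(1.0)

    def test_24h_shift_leaves_vector_unchanged(self):
        rng = np.random.default_rng(0)
        values = 120 + rng.normal(0, 10, 30)
        s1 = make_series(values, start=T0)
        s2 = make_series(values, start=T0 + pd.Timedelta(days=7))
        f1 = build_features(s1, [], self.profile, self.params, pd.Timestamp(s1.times[-1]))
        f2 = build_features(s2, [], self.profile, self.params, pd.Timestamp(s2.times[-1]))
        same_dow = dict(zip(f1.names, f1.values))["day_of_week"] == dict(zip(f2.names, f2.values))["day_of_week"]
        assert same_dow
        assert np.allclose(f1.values, f2.values)

    def test_gap_in_history_raises(self):
        minutes = [0, 5, 10, 45, 50, 55, 60, 65]
        times = np.array([T0 + pd.Timedelta(minutes=m) for m in minutes], dtype="datetime64[s]")
        from cgmforecast.core import GlucoseSeries

        s = GlucoseSeries(times, np.full(len(times), 120.0))
        with pytest.raises(FeatureUnavailableError):
            build_features(s, [], self.profile, self.params, pd.Timestamp(s.times[-1]))

    def test_activity_feature_reflects_recent_exercise(self):
        s = make_series([120.0] * 20)
        t_end = pd.Timestamp(s.times[-1])
        ev = [EventRecord(t=t_end - pd.Timedelta(minutes=30), kind="exercise", intensity=2, duration=30)]
        fv = build_features(s, ev, self.profile, self.params, t_end)
        assert dict(zip(fv.names, fv.values))["activity"] == 2.0
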