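"""The no-intervention trend adjustment: linear forecast, firing conditions,
and convex blending."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cgmforecast.adjustment import (
    AdjustmentConfig,
    TrendUnavailableError,
    apply_adjustment,
    blend_predictions,
    default_weight_schedule,
    linear_trend_forecast,
    should_adjust,
)
from cgmforecast.core import EventRecord, PatientProfile
from cgmforecast.forecast import HORIZONS, PredictionCurve, interpolate_curve
from cgmforecast.simulate import SimParams, simulate_patient

from conftest import T0, make_series

PROFILE = PatientProfile(patient_id="p")


class TestLinearTrendForecast:
    def test_constant_series_projects_itself(self):
        s = make_series([150.0] * 10)
        for h in HORIZONS:
            assert linear_trend_forecast(s, pd.Timestamp(s.times[-1]), h) == pytest.approx(150.0)

    def test_exact_line_continues(self):
        s = make_series(100 + 5.0 * np.arange(10))  # +1 mg/dL per minute
        got = linear_trend_forecast(s, pd.Timestamp(s.times[-1]), 30)
        assert got == pytest.approx(s.values[-1] + 30.0)

    def test_matches_closed_form_ols_on_five_points(self):
        values = np.array([100.0, 104.0, 101.0, 107.0, 105.0])
        s = make_series(values)
        t = np.array([-20.0, -15.0, -10.0, -5.0, 0.0])
        slope = np.sum((t - t.mean()) * (values - values.mean())) / np.sum((t - t.mean()) ** 2)
        intercept = values.mean() - slope * t.mean()
        expected = intercept + slope * 30.0
        got = linear_trend_forecast(s, pd.Timestamp(s.times[-1]), 30)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_too_few_samples_unavailable(self):
        s = make_series([100.0, 110.0])
        with pytest.raises(TrendUnavailableError):
            linear_trend_forecast(s, pd.Timestamp(s.times[-1]), 30)

    def test_clamped_to_sensor_range(self):
        s = make_series(300 + 10.0 * np.arange(10))
        assert linear_trend_forecast(s, pd.Timestamp(s.times[-1]), 60) == 400.0


class TestShouldAdjust:
    def test_recent_meal_vetoes(self):
        s = make_series(150 + 4.0 * np.arange(13))  # rising steadily
        t0 = pd.Timestamp(s.times[-1])
        events = [EventRecord(t=t0 - pd.Timedelta(minutes=20), kind="meal", carbs=40)]
        decision = should_adjust(s, events, PROFILE, t0)
        assert not decision.no_recent_events
        assert not decision.apply

    def test_old_event_does_not_veto(self):
        s = make_series(150 + 4.0 * np.arange(13))
        t0 = pd.Timestamp(s.times[-1])
        events = [EventRecord(t=t0 - pd.Timedelta(minutes=60), kind="bolus", insulin_units=2)]
        assert should_adjust(s, events, PROFILE, t0).no_recent_events

    def test_flat_midrange_not_trending_out(self):
        s = make_series([120.0] * 13)
        decision = should_adjust(s, [], PROFILE, pd.Timestamp(s.times[-1]))
        assert not decision.trending_out
        assert not decision.apply

    def test_rising_past_range_with_no_events_fires(self):
        # 30 min of steady rise ending at 185 mg/dL, no events, no reversals
        s = make_series(185 - 1.5 * np.arange(12, -1, -1))
        t0 = pd.Timestamp(s.times[-1])
        events = [EventRecord(t=t0 - pd.Timedelta(minutes=60), kind="meal", carbs=30)]
        decision = should_adjust(s, events, PROFILE, t0)
        assert decision.trending_out
        assert decision.no_direction_change
        assert decision.no_recent_events
        assert decision.apply

    def test_trend_reversal_vetoes(self):
        # fell for 45 min then turned upward 15 min ago: a recent reversal
        values = np.concatenate([200 - 5.0 * np.arange(10), [160.0, 170.0, 185.0]])
        s = make_series(values)
        decision = should_adjust(s, [], PROFILE, pd.Timestamp(s.times[-1]))
        assert not decision.no_direction_change

    def test_exercise_does_not_veto(self):
        s = make_series(185 - 1.5 * np.arange(12, -1, -1))
        t0 = pd.Timestamp(s.times[-1])
        events = [EventRecord(t=t0 - pd.Timedelta(minutes=10), kind="exercise", intensity=2, duration=30)]
        assert should_adjust(s, events, PROFILE, t0).no_recent_events


class TestBlend:
    def test_weight_zero_keeps_model(self):
        assert blend_predictions(150.0, 190.0, 0.0) == 150.0

    def test_weight_one_takes_linear(self):
        assert blend_predictions(150.0, 190.0, 1.0) == 190.0

    def test_midpoint(self):
        assert blend_predictions(150.0, 190.0, 0.5) == 170.0

    def test_weight_out_of_range_rejected(self):
        for w in (-0.1, 1.1):
            with pytest.raises(ValueError):
                blend_predictions(150.0, 190.0, w)

    @given(
        st.floats(min_value=40, max_value=400),
        st.floats(min_value=40, max_value=400),
        st.floats(min_value=0, max_value=1),
    )
    def test_convexity(self, model, linear, w):
        out = blend_predictions(model, linear, w)
        assert min(model, linear) - 1e-9 <= out <= max(model, linear) + 1e-9

    def test_weight_schedule_grows_with_horizon(self):
        w = default_weight_schedule()
        assert w[15] == pytest.approx(0.25) and w[60] == pytest.approx(0.6)
        assert all(w[a] < w[b] for a, b in zip(HORIZONS, HORIZONS[1:]))


class TestApplyAdjustment:
    def _curve(self, s, anchors):
        t0 = pd.Timestamp(s.times[-1])
        return PredictionCurve(
            t0=t0,
            current=float(s.values[-1]),
            anchors=anchors,
            interpolated=interpolate_curve(float(s.values[-1]), anchors),
        )

    def test_out_trending_blend_never_cancels_the_trend(self):
        # model optimistically predicts normalisation; linear continues up
        s = make_series(185 - 1.5 * np.arange(12, -1, -1))
        model_anchors = {h: 175.0 for h in HORIZONS}
        curve = self._curve(s, model_anchors)
        out = apply_adjustment(curve, s, [], PROFILE)
        assert out.adjusted
        for h in HORIZONS:
            linear = linear_trend_forecast(s, curve.t0, h)
            assert min(175.0, linear) <= out.anchors[h] <= max(175.0, linear)
            # relative to the linear forecast the blend is never pulled back
            # inside the range further than the model's own optimism
            assert out.anchors[h] >= min(175.0, linear)

    def test_no_fire_keeps_curve_untouched(self):
        s = make_series([120.0] * 13)
        curve = self._curve(s, {h: 120.0 for h in HORIZONS})
        out = apply_adjustment(curve, s, [], PROFILE)
        assert out is curve and not out.adjusted

    def test_never_fires_on_quiet_midrange_simulation(self):
        params = SimParams(
            seed=17, meal_rate=0.0, exercise_rate=0.0, gap_rate=0.0,
            circadian_amplitude=0.0, noise_sd=2.0, process_noise_sd=0.0,
        )
        series, events, profile, _ = simulate_patient(params, 2)
        fired = 0
        for i in range(12, len(series), 4):
            decision = should_adjust(series, events, profile, pd.Timestamp(series.times[i]))
            fired += decision.apply
        assert fired == 0
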