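"""Glucose-control metrics and the usage-stratified statistical table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

from cgmforecast.core import EmptySeriesError, GlucoseSeries
from cgmforecast.metrics import (
    DayRecord,
    DomainError,
    METRICS,
    bonferroni_alpha,
    gmi,
    hbgi_category,
    lbgi_category,
    lbgi_hbgi,
    metrics_row,
    risk_transform,
    session_bin,
    split_days,
    time_in_range,
    usage_stratified_table,
    welch_one_sided,
)
from cgmforecast.simulate import SimParams, generate_cohort

from conftest import T0, make_series


class TestTimeInRange:
    def test_all_inside(self):
        assert time_in_range(make_series([100.0] * 10)) == 100.0

    def test_half_low(self):
        assert time_in_range(make_series([60.0] * 5 + [100.0] * 5)) == 50.0

    def test_bounds_inclusive(self):
        assert time_in_range(make_series([70.0, 180.0])) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(EmptySeriesError):
            time_in_range(GlucoseSeries(np.array([], dtype="datetime64[s]"), []))


class TestGmi:
    @pytest.mark.parametrize(
        "mean_bg,expected",
        [(154.0, 6.99), (150.7, 6.91), (145.6, 6.79), (141.6, 6.70)],
    )
    def test_group_mean_worked_examples(self, mean_bg, expected):
        assert gmi(mean_bg) == pytest.approx(expected, abs=0.005)

    def test_intercept_identity(self):
        # formula-only identity at the (out-of-domain) zero limit
        assert gmi(1e-9) == pytest.approx(3.31, abs=0.01)

    def test_non_positive_rejected(self):
        with pytest.raises(DomainError):
            gmi(0.0)

    @given(st.floats(min_value=40, max_value=400), st.floats(min_value=0.5, max_value=50))
    def test_strictly_increasing(self, mean_bg, bump):
        assert gmi(mean_bg + bump) > gmi(mean_bg) or bump < 0.45  # 2-dp rounding plateau
        assert (3.31 + 0.02392 * (mean_bg + bump)) > (3.31 + 0.02392 * mean_bg)


class TestRiskTransform:
    def test_zero_crossing_near_112_5(self):
        f = lambda bg: risk_transform(bg)[0]
        root = optimize.brentq(f, 50, 300)
        assert 112 < root < 113

    def test_low_reading_is_pure_hypo_risk(self):
        _, rl, rh = risk_transform(50)
        assert rl == pytest.approx(22.5, abs=0.1)
        assert rh == 0.0

    def test_high_reading_is_pure_hyper_risk(self):
        _, rl, rh = risk_transform(400)
        assert rh > 0 and rl == 0.0

    def test_one_sided_product_zero(self):
        for bg in (40, 80, 112, 113, 200, 400):
            _, rl, rh = risk_transform(bg)
            assert rl * rh == 0.0 and rl >= 0 and rh >= 0

    def test_out_of_domain_rejected(self):
        for bg in (10, 700):
            with pytest.raises(DomainError):
                risk_transform(bg)


class TestRiskIndices:
    def test_constant_series_at_crossing_is_riskless(self):
        f = lambda bg: risk_transform(bg)[0]
        root = optimize.brentq(f, 50, 300)
        lbgi, hbgi = lbgi_hbgi(make_series([root] * 20))
        assert lbgi < 1e-6 and hbgi < 1e-6

    def test_category_thresholds(self):
        assert hbgi_category(5.0) == "moderate risk"
        assert hbgi_category(4.4) == "low risk"
        assert hbgi_category(9.5) == "high risk"
        assert lbgi_category(0.9) == "minimal risk"
        assert lbgi_category(2.0) == "low risk"
        assert lbgi_category(6.0) == "high risk"

    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, order):
        base = [55.0, 80.0, 100.0, 120.0, 160.0, 220.0, 300.0, 65.0]
        shuffled = [base[i] for i in order]
        assert lbgi_hbgi(make_series(shuffled)) == pytest.approx(lbgi_hbgi(make_series(base)))


class TestBonferroni:
    def test_printed_truncated_threshold(self):
        assert bonferroni_alpha(0.01, 36) == pytest.approx(0.00027, abs=1e-12)

    def test_other_precision(self):
        assert bonferroni_alpha(0.05, 10, sig_digits=2) == pytest.approx(0.005)


class TestWelch:
    def test_identical_groups_p_half(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert welch_one_sided(a, a.copy(), "less") == pytest.approx(0.5)

    def test_matches_closed_form_on_3v3_toy(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        # textbook Welch statistic and Welch-Satterthwaite df, evaluated by hand
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        expected = stats.t.cdf(t, df)
        assert welch_one_sided(a, b, "less") == pytest.approx(expected, rel=1e-10)

    def test_tiny_group_reported_unavailable(self):
        assert math.isnan(welch_one_sided(np.array([1.0]), np.array([1.0, 2.0]), "less"))


class TestSessionBins:
    @pytest.mark.parametrize("n,expected", [(0, "0"), (1, "1-5"), (5, "1-5"), (6, "6-10"), (10, "6-10"), (11, ">10")])
    def test_bin_edges(self, n, expected):
        assert session_bin(n) == expected

    @given(st.integers(min_value=0, max_value=10_000))
    def test_bins_partition_non_negative_integers(self, n):
        assert sum(session_bin(n) == b for b in ("0", "1-5", "6-10", ">10")) == 1


def _day(sessions: int, values, date="2019-03-02") -> DayRecord:
    return DayRecord(
        date=pd.Timestamp(date),
        patient_id="p",
        sessions=sessions,
        series=make_series(values, start=pd.Timestamp(f"{date} 00:00")),
    )


class TestStratifiedTable:
    def test_identical_groups_give_p_half(self):
        days = [_day(0, [100 + k] * 12) for k in range(4)] + [
            _day(3, [100 + k] * 12) for k in range(4)
        ]
        table = usage_stratified_table(days)
        for m in METRICS:
            p = table.p_zero["1-5"][m]
            assert p == pytest.approx(0.5)

    def test_cohort_end_to_end_shapes(self):
        cohort = generate_cohort(SimParams(), n_patients=3, days=30, master_seed=9)
        days = []
        for pat in cohort:
            days += split_days(pat.series, pat.details.session_counts, pat.profile.patient_id)
        table = usage_stratified_table(days)
        assert sum(table.group_sizes.values()) == len(days)
        assert table.alpha_corrected == pytest.approx(0.00027)
        frame = table.to_frame()
        assert set(METRICS) <= set(frame.columns)
        for b, by_metric in table.p_zero.items():
            for m, p in by_metric.items():
                assert math.isnan(p) or 0.0 <= p <= 1.0

    def test_single_group_rejected(self):
        days = [_day(0, [100.0] * 12) for _ in range(3)]
        with pytest.raises(ValueError):
            usage_stratified_table(days)

    def test_metrics_row_values(self):
        row = metrics_row(make_series([100.0, 150.0, 200.0]))
        assert row.mean_bg == pytest.approx(150.0)
        assert row.tir == pytest.approx(200.0 / 3)
        assert row.gmi == gmi(150.0)
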