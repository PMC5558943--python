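"""Screening, interpolation, and calendar-weighted aggregation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trendlag as tl
from trendlag.preprocess import SeriesCategory, _span_months
from trendlag.series import SeriesError

from helpers import make_weekly


def weeks_spanning(n_months: int, start: str = "2004-01-04") -> int:
    """Number of weeks from ``start`` whose span touches exactly n_months."""
    first = pd.Timestamp(start)
    n = 1
    while _span_months(make_weekly(np.zeros(n + 1), start=start)) <= n_months:
        n += 1
    assert _span_months(make_weekly(np.zeros(n), start=start)) == n_months
    return n


class TestCategorize:
    def test_all_missing_is_no_data(self):
        assert tl.categorize(make_weekly([np.nan] * 10)) == SeriesCategory.NO_DATA

    def test_no_missing_is_complete(self):
        assert tl.categorize(make_weekly(np.arange(10))) == SeriesCategory.COMPLETE

    def test_isolated_spikes_are_peaks_only(self):
        values = np.full(200, np.nan)
        values[[10, 50, 90, 130, 170]] = 80.0
        assert tl.categorize(make_weekly(values)) == SeriesCategory.PEAKS_ONLY

    def test_moderate_missingness_is_incomplete(self):
        values = np.arange(100, dtype=float)
        values[40:45] = np.nan
        assert tl.categorize(make_weekly(values)) == SeriesCategory.INCOMPLETE


class TestCropMargins:
    def test_removes_marginal_runs_only(self):
        s = make_weekly([np.nan, np.nan, 5, np.nan, 7, np.nan])
        out = tl.crop_margins(s)
        assert np.array_equal(out.values, [5, np.nan, 7], equal_nan=True)

    def test_identity_without_marginal_missing(self):
        s = make_weekly([5, np.nan, 7])
        out = tl.crop_margins(s)
        assert np.array_equal(out.values, s.values, equal_nan=True)

    def test_idempotent(self):
        s = make_weekly([np.nan, 1, np.nan, 2, np.nan])
        once = tl.crop_margins(s)
        twice = tl.crop_margins(once)
        assert np.array_equal(once.values, twice.values, equal_nan=True)

    def test_all_missing_raises(self):
        with pytest.raises(SeriesError):
            tl.crop_margins(make_weekly([np.nan, np.nan]))


class TestInclusion:
    def test_37_month_complete_series_passes(self):
        n = weeks_spanning(37)
        report = tl.check_inclusion(make_weekly(np.full(n, 50.0)))
        assert report.passed and report.n_months == 37

    def test_35_month_span_fails_min_span(self):
        n = weeks_spanning(35)
        report = tl.check_inclusion(make_weekly(np.full(n, 50.0)))
        assert not report.passed and report.reasons == ("min_span",)

    def test_eleven_week_gap_fails_max_run(self):
        n = weeks_spanning(48)
        values = np.full(n, 50.0)
        values[60:71] = np.nan  # 11 consecutive missing weeks
        report = tl.check_inclusion(make_weekly(values))
        assert not report.passed and "max_run" in report.reasons

    def test_ten_week_gap_is_tolerated(self):
        n = weeks_spanning(48)
        values = np.full(n, 50.0)
        values[60:70] = np.nan
        assert tl.check_inclusion(make_weekly(values)).passed

    def test_excess_missing_fraction_fails(self):
        n = weeks_spanning(48)
        values = np.full(n, 50.0)
        miss = np.linspace(5, n - 5, int(0.12 * n), dtype=int)
        values[miss] = np.nan
        report = tl.check_inclusion(make_weekly(values))
        assert "max_missing" in report.reasons


class TestInterpolate:
    def test_midpoint(self):
        out = tl.interpolate(make_weekly([10, np.nan, 20]))
        assert np.array_equal(out.values, [10, 15, 20])

    def test_equal_spacing_over_long_gap(self):
        out = tl.interpolate(make_weekly([10, np.nan, np.nan, 40]))
        assert np.array_equal(out.values, [10, 20, 30, 40])

    def test_marginal_missing_rejected(self):
        with pytest.raises(SeriesError):
            tl.interpolate(make_weekly([np.nan, 10, 20]))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_linear_series_reconstructed_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        line = np.linspace(10, 90, n)
        knocked = line.copy()
        # interior knockouts only; keep both endpoints
        drop = rng.choice(np.arange(1, n - 1), size=10, replace=False)
        knocked[drop] = np.nan
        out = tl.interpolate(make_weekly(knocked))
        np.testing.assert_allclose(out.values, line, atol=1e-9)


def aggregate_daily_oracle(series: tl.WeeklySeries, min_days: int = 15):
    """Independent reference: expand weeks to days, average within months."""
    days, values = [], []
    for start, value in zip(series.start_dates, series.values):
        for offset in range(7):
            days.append(start + pd.Timedelta(days=offset))
            values.append(value)
    frame = pd.DataFrame({"day": days, "value": values})
    frame["month"] = frame["day"].dt.to_period("M")
    grouped = frame.groupby("month")["value"].agg(["mean", "count"])
    months = list(grouped.index)
    while months and grouped.loc[months[0], "count"] < min_days:
        months.pop(0)
    while months and grouped.loc[months[-1], "count"] < min_days:
        months.pop()
    return grouped.loc[months, "mean"].to_numpy(), months


class TestAggregateToMonthly:
    def test_constant_series_is_conserved(self):
        out = tl.aggregate_to_monthly(make_weekly(np.full(60, 42.0)))
        assert np.allclose(out.values, 42.0)

    def test_matches_daily_expansion_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(30, 200))
            start = pd.Timestamp("2004-01-04") + pd.Timedelta(days=7 * int(rng.integers(0, 200)))
            series = make_weekly(rng.integers(0, 101, n).astype(float), start=str(start.date()))
            got = tl.aggregate_to_monthly(series)
            expected, months = aggregate_daily_oracle(series)
            assert list(got.months) == months
            np.testing.assert_allclose(got.values, expected, atol=1e-9)

    def test_output_bounded_by_weekly_extremes(self, rng):
        series = make_weekly(rng.integers(0, 101, 120).astype(float))
        out = tl.aggregate_to_monthly(series)
        assert out.values.min() >= series.values.min() - 1e-12
        assert out.values.max() <= series.values.max() + 1e-12

    def test_rejects_missing_values(self):
        with pytest.raises(SeriesError):
            tl.aggregate_to_monthly(make_weekly([1, np.nan, 3]))


class TestPrepare:
    def test_full_pipeline_on_generated_series(self):
        spec = tl.GenSpec(
            arima_orders=(1, 0, 0, 0, 0, 0),
            ar=(0.6,),
            n_weeks=200,
            missing_fraction=0.05,
            max_missing_run=4,
            seed=7,
        )
        weekly = tl.generate_search_series(spec)
        monthly, report = tl.prepare(weekly)
        assert report.passed
        assert monthly.n_months >= 36
        assert not np.isnan(monthly.values).any()

    def test_failing_series_raises_with_reason(self):
        short = make_weekly(np.full(20, 50.0))
        with pytest.raises(SeriesError, match="min_span"):
            tl.prepare(short)
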