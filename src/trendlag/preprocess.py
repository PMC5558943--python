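"""Preparation of weekly search-volume series for monthly time-series analysis.

The pipeline order is fixed: margin cropping, categorization / inclusion
screening, linear interpolation of interior gaps, and calendar-weighted
aggregation to months.  The inclusion rules mirror the screening applied to
raw search-volume exports: a retained series must span at least 36 calendar
months, have at most 10% missing weekly values, and no missing run longer
than 10 consecutive weeks (about 2 months).  Missing fractions are computed
after margin cropping, the only self-consistent reading when spans are
reported post-crop.

Weekly-to-monthly aggregation is an exact day-count weighted average: each
week contributes to a month in proportion to how many of its 7 days fall in
that month (proleptic Gregorian arithmetic, no 7/30 shortcuts).  Margin
months covered by fewer than ``min_days`` days (default 15) are dropped so
no month is estimated from a sliver of data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .series import MonthlySeries, SeriesError, WeeklySeries

__all__ = [
    "SeriesCategory",
    "InclusionReport",
    "categorize",
    "crop_margins",
    "check_inclusion",
    "interpolate",
    "aggregate_to_monthly",
    "prepare",
]

#: Inclusion rule identifiers reported when a series fails screening.
MIN_SPAN_MONTHS = 36
MAX_MISSING_FRACTION = 0.10
MAX_MISSING_RUN_WEEKS = 10


class SeriesCategory(str, Enum):
    """Availability categories of a raw weekly series."""

    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    PEAKS_ONLY = "peaks_only"
    NO_DATA = "no_data"


@dataclass(frozen=True)
class InclusionReport:
    """Outcome of the inclusion screening; ``passed`` iff no rule violated."""

    passed: bool
    n_months: int
    missing_fraction_weekly: float
    longest_missing_run_weeks: int
    reasons: tuple[str, ...]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of True values."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def categorize(
    series: WeeklySeries,
    sparsity_threshold: float = 0.10,
    max_peak_run: int = 2,
) -> SeriesCategory:
    """Assign one of the four availability categories.

    ``peaks_only`` operationalizes "single peaks, but (mostly) no further
    data": the non-missing fraction is at most ``sparsity_threshold`` and
    every present run is at most ``max_peak_run`` weeks long.
    """
    mask = series.missing_mask
    if mask.all():
        return SeriesCategory.NO_DATA
    if not mask.any():
        return SeriesCategory.COMPLETE
    present = ~mask
    if np.mean(present) <= sparsity_threshold and all(
        length <= max_peak_run for _, length in _runs(present)
    ):
        return SeriesCategory.PEAKS_ONLY
    return SeriesCategory.INCOMPLETE


def crop_margins(series: WeeklySeries) -> WeeklySeries:
    """Remove leading and trailing missing runs; interior gaps are untouched.

    Idempotent.  Raises :class:`SeriesError` if nothing remains.
    """
    mask = series.missing_mask
    present = np.flatnonzero(~mask)
    if present.size == 0:
        raise SeriesError("series is all-missing after cropping")
    return series.slice(int(present[0]), int(present[-1]) + 1)


def _span_months(series: WeeklySeries) -> int:
    """Calendar months touched between the first week start and last week end."""
    first = series.start_dates[0].to_period("M")
    last = (series.start_dates[-1] + pd.Timedelta(days=6)).to_period("M")
    return int(last.ordinal - first.ordinal + 1)


def check_inclusion(series: WeeklySeries) -> InclusionReport:
    """Apply the three inclusion rules to an already-cropped series."""
    mask = series.missing_mask
    n_months = _span_months(series)
    frac = float(np.mean(mask))
    longest = max((length for _, length in _runs(mask)), default=0)
    reasons = []
    if n_months < MIN_SPAN_MONTHS:
        reasons.append("min_span")
    if frac > MAX_MISSING_FRACTION:
        reasons.append("max_missing")
    if longest > MAX_MISSING_RUN_WEEKS:
        reasons.append("max_run")
    return InclusionReport(
        passed=not reasons,
        n_months=n_months,
        missing_fraction_weekly=frac,
        longest_missing_run_weeks=int(longest),
        reasons=tuple(reasons),
    )


def interpolate(series: WeeklySeries) -> WeeklySeries:
    """Linearly interpolate interior missing weeks.

    Requires a cropped series (no marginal missingness); present values are
    unchanged and the result has no missing entries.
    """
    mask = series.missing_mask
    if mask.size and (mask[0] or mask[-1]):
        raise SeriesError("marginal missing values present; crop before interpolating")
    if not mask.any():
        return series
    idx = np.arange(len(mask))
    values = series.values.copy()
    values[mask] = np.interp(idx[mask], idx[~mask], values[~mask])
    return series.with_values(values)


def aggregate_to_monthly(series: WeeklySeries, min_days: int = 15) -> MonthlySeries:
    """Day-count weighted aggregation of a fully interpolated weekly series.

    Month value = sum_w(value_w * d_wm) / sum_w(d_wm) where ``d_wm`` is the
    number of week *w*'s 7 days falling in calendar month *m*.  Margin
    months with fewer than ``min_days`` covered days are dropped; the
    result is contiguous.
    """
    if series.missing_mask.any():
        raise SeriesError("aggregate requires a series without missing values")
    num: dict[pd.Period, float] = {}
    den: dict[pd.Period, int] = {}
    for start, value in zip(series.start_dates, series.values):
        month = start.to_period("M")
        days_left = int((month.end_time.normalize() - start).days) + 1
        d_first = min(7, days_left)
        for period, days in ((month, d_first), (month + 1, 7 - d_first)):
            if days:
                num[period] = num.get(period, 0.0) + value * days
                den[period] = den.get(period, 0) + days
    months = sorted(den)
    while months and den[months[0]] < min_days:
        months.pop(0)
    while months and den[months[-1]] < min_days:
        months.pop()
    if not months:
        raise SeriesError("no month retains the minimum day coverage")
    values = np.array([num[m] / den[m] for m in months])
    return MonthlySeries(
        pd.PeriodIndex(months, freq="M"), values, label=series.label, region=series.region
    )


def prepare(series: WeeklySeries, min_days: int = 15) -> tuple[MonthlySeries, InclusionReport]:
    """Full preparation: crop, screen, interpolate, aggregate.

    The monthly series is returned together with the inclusion report; a
    series failing screening raises :class:`SeriesError`.
    """
    cropped = crop_margins(series)
    report = check_inclusion(cropped)
    if not report.passed:
        raise SeriesError(f"series fails inclusion rules: {', '.join(report.reasons)}")
    return aggregate_to_monthly(interpolate(cropped), min_days=min_days), report
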