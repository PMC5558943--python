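"""Core time-series containers and CSV input/output.

Two containers run through the whole pipeline:

* :class:`WeeklySeries` — normalized search-volume values on a weekly grid
  (Google-Trends-export style: values 0–100, one row per week start date,
  a blank value meaning "insufficient data").  Missing entries are held as
  ``NaN`` alongside an explicit boolean mask, never as 0, because a true 0
  and "no data" are different observations.
* :class:`MonthlySeries` — calendar-month-indexed values, either aggregated
  search volumes or outcome counts for a population stratum.

CSV dialects match the upstream conventions: weekly files have a
``week,value`` header (optionally preceded by preamble lines, as in raw
exports), monthly files are ``year,month,value`` and stratified count files
``year,month,stratum,count``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "WeeklySeries",
    "MonthlySeries",
    "read_weekly_csv",
    "write_weekly_csv",
    "read_monthly_csv",
    "write_monthly_csv",
    "read_counts_csv",
    "write_counts_csv",
]


class SeriesError(ValueError):
    """Invalid series construction or operation."""


@dataclass(frozen=True)
class WeeklySeries:
    """Weekly series of normalized search volumes with explicit missingness.

    Parameters
    ----------
    start_dates
        Week start dates, strictly increasing with constant 7-day spacing.
    values
        Float array; ``NaN`` marks a missing week.  Present values must lie
        in [0, 100].
    label, region
        Search term and geographic region the series belongs to.
    """

    start_dates: pd.DatetimeIndex
    values: np.ndarray
    label: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.start_dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "start_dates", dates)
        object.__setattr__(self, "values", values)
        if len(dates) != len(values):
            raise SeriesError("dates and values differ in length")
        if len(dates) == 0:
            raise SeriesError("empty weekly series")
        if len(dates) > 1:
            deltas = np.diff(dates.view("int64"))
            if not np.all(deltas == deltas[0]) or deltas[0] != 7 * 86400 * 10**9:
                raise SeriesError("week starts must be strictly increasing at 7-day spacing")
        present = values[~np.isnan(values)]
        if present.size and (present.min() < 0 or present.max() > 100):
            raise SeriesError("present values must lie in [0, 100]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_weeks(self) -> int:
        return len(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing_mask))

    def with_values(self, values: np.ndarray) -> "WeeklySeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def slice(self, start: int, stop: int) -> "WeeklySeries":
        return WeeklySeries(
            self.start_dates[start:stop], self.values[start:stop], self.label, self.region
        )


@dataclass(frozen=True)
class MonthlySeries:
    """Contiguous calendar-month series (volumes or counts)."""

    months: pd.PeriodIndex
    values: np.ndarray
    label: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        months = pd.PeriodIndex(self.months, freq="M")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "values", values)
        if len(months) != len(values):
            raise SeriesError("months and values differ in length")
        if len(months) == 0:
            raise SeriesError("empty monthly series")
        if len(months) > 1 and not np.all(np.diff(months.asi8) == 1):
            raise SeriesError("months must be contiguous")
        if np.isnan(values).any():
            raise SeriesError("monthly series must not contain missing values")

    @property
    def n_months(self) -> int:
        return len(self.values)

    def align(self, other: "MonthlySeries") -> tuple["MonthlySeries", "MonthlySeries"]:
        """Inner-join two monthly series on their common month span."""
        common = self.months.intersection(other.months)
        if len(common) == 0:
            raise SeriesError("series have no overlapping months")
        a = self.values[self.months.get_indexer(common)]
        b = other.values[other.months.get_indexer(common)]
        return (
            MonthlySeries(common, a, self.label, self.region),
            MonthlySeries(common, b, other.label, other.region),
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_weekly_csv(
    path: str | Path,
    label: str = "",
    region: str = "",
    zero_as_missing: bool = False,
) -> WeeklySeries:
    """Read a weekly search-volume CSV.

    Preamble lines before a header starting with ``week`` (case-insensitive,
    e.g. the ``Week,...`` header of raw exports) are skipped.  Blank values
    are missing; with ``zero_as_missing`` literal zeros are treated as
    missing too (the export conflates 0 with "insufficient data").
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.strip().lower().startswith("week"):
            header_idx = i
            break
    if header_idx is None:
        raise SeriesError(f"{path}: no 'week' header found")
    df = pd.read_csv(path, skiprows=header_idx)
    df.columns = [c.strip().lower() for c in df.columns]
    dates = pd.to_datetime(df.iloc[:, 0])
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if zero_as_missing:
        values = np.where(values == 0, np.nan, values)
    return WeeklySeries(pd.DatetimeIndex(dates), values, label=label, region=region)


def write_weekly_csv(series: WeeklySeries, path: str | Path) -> None:
    """Write ``week,value`` CSV; missing weeks get a blank value."""
    with open(path, "w") as fh:
        fh.write("week,value\n")
        for date, value in zip(series.start_dates, series.values):
            text = "" if np.isnan(value) else format(value, "g")
            fh.write(f"{date.date().isoformat()},{text}\n")


def read_monthly_csv(path: str | Path, label: str = "", region: str = "") -> MonthlySeries:
    df = pd.read_csv(path)
    months = pd.PeriodIndex(
        [pd.Period(year=int(y), month=int(m), freq="M") for y, m in zip(df["year"], df["month"])]
    )
    return MonthlySeries(months, df["value"].to_numpy(dtype=float), label=label, region=region)


def write_monthly_csv(series: MonthlySeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("year,month,value\n")
        for period, value in zip(series.months, series.values):
            fh.write(f"{period.year},{period.month},{format(value, 'g')}\n")


def read_counts_csv(path: str | Path, region: str = "") -> dict[str, MonthlySeries]:
    """Read a stratified ``year,month,stratum,count`` CSV into one series per stratum."""
    df = pd.read_csv(path)
    out: dict[str, MonthlySeries] = {}
    for stratum, group in df.groupby("stratum", sort=True):
        group = group.sort_values(["year", "month"])
        months = pd.PeriodIndex(
            [
                pd.Period(year=int(y), month=int(m), freq="M")
                for y, m in zip(group["year"], group["month"])
            ]
        )
        out[str(stratum)] = MonthlySeries(
            months, group["count"].to_numpy(dtype=float), label=str(stratum), region=region
        )
    return out


def write_counts_csv(strata: dict[str, MonthlySeries], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("year,month,stratum,count\n")
        for stratum in sorted(strata):
            series = strata[stratum]
            for period, value in zip(series.months, series.values):
                fh.write(f"{period.year},{period.month},{stratum},{format(value, 'g')}\n")
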