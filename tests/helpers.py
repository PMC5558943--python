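"""Shared fixture builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

import trendlag as tl

SUNDAY = "2004-01-04"


def make_weekly(values, start: str = SUNDAY, label: str = "term", region: str = "XX") -> tl.WeeklySeries:
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="7D")
    return tl.WeeklySeries(dates, values, label=label, region=region)


def make_monthly(values, start: str = "2004-01", label: str = "m", region: str = "XX") -> tl.MonthlySeries:
    values = np.asarray(values, dtype=float)
    months = pd.period_range(start, periods=len(values), freq="M")
    return tl.MonthlySeries(months, values, label=label, region=region)


def ar1_monthly(n: int, seed: int, phi: float = 0.6, level: float = 50.0) -> tl.MonthlySeries:
    spec = tl.GenSpec(arima_orders=(1, 0, 0, 0, 0, 0), ar=(phi,), level=level, seed=seed)
    return tl.generate_monthly_volume(spec, n).series
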