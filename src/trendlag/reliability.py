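"""Pull-to-pull reliability of repeated search-volume requests.

Repeated requests of the same term on different days return slightly
different normalized series.  Agreement across ``k`` pulls observed at
``n`` time points is quantified with the two-way intraclass correlation for
consistency — ICC(C,1) for a single pull and ICC(C,k) for the average of
the ``k`` pulls in the McGraw–Wong taxonomy (the consistency formula is
algebraically identical under the two-way random and two-way mixed models).
Confidence intervals come from the F ratio of the row and residual mean
squares; the interval method is the standard F-based one, adopted here as
an explicit choice since no alternative is canonical for this design.

Negative ICC estimates are reported as-is rather than truncated at zero,
so degenerate cases stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import SeriesError, WeeklySeries

__all__ = ["PullMatrix", "ReliabilityResult", "icc_consistency", "average_pulls", "build_pull_matrix"]


@dataclass(frozen=True)
class PullMatrix:
    """Rectangular pull data: rows are time points, columns are pulls."""

    values: np.ndarray
    label: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 3 or values.shape[1] < 2:
            raise ValueError("pull matrix needs at least 3 time points and 2 pulls")
        if np.isnan(values).any():
            raise ValueError("pull matrix must have no missing cells; align and crop first")


@dataclass(frozen=True)
class ReliabilityResult:
    icc_single: float
    icc_average: float
    ci_single: tuple[float, float]
    ci_average: tuple[float, float]
    n: int
    k: int
    alpha: float


def icc_consistency(m: PullMatrix, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(C,1) and ICC(C,k) with two-sided F-based confidence intervals.

    From the two-way ANOVA decomposition (rows = time points, columns =
    pulls): ``icc_single = (MS_R - MS_E) / (MS_R + (k-1) MS_E)`` and
    ``icc_average = (MS_R - MS_E) / MS_R``.  Interval endpoints transform
    the F ratio ``MS_R / MS_E`` with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_e <= 0 and ms_r <= 0:
        raise SeriesError("ICC undefined: no row variance and no residual variance")
    if ms_e == 0:
        icc1, icck = 1.0, 1.0
        ci1 = cik = (1.0, 1.0)
    else:
        icc1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
        icck = (ms_r - ms_e) / ms_r
        f_obs = ms_r / ms_e
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_lower = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_upper = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci1 = ((f_lower - 1) / (f_lower + k - 1), (f_upper - 1) / (f_upper + k - 1))
        cik = (1 - 1 / f_lower, 1 - 1 / f_upper)
    return ReliabilityResult(
        icc_single=float(icc1),
        icc_average=float(icck),
        ci_single=(float(ci1[0]), float(ci1[1])),
        ci_average=(float(cik[0]), float(cik[1])),
        n=n,
        k=k,
        alpha=alpha,
    )


def build_pull_matrix(pulls: list[WeeklySeries], max_missing_pulls: int = 0) -> PullMatrix:
    """Align pulls on their common dates and drop incomplete rows.

    Pulls are inner-joined on week start dates (repeated requests can be
    asynchronous); a time point is kept only if at most ``max_missing_pulls``
    pulls miss it, and remaining missing cells cause the row to be dropped.
    """
    if len(pulls) < 2:
        raise ValueError("at least 2 pulls are required")
    common = pulls[0].start_dates
    for p in pulls[1:]:
        common = common.intersection(p.start_dates)
    if len(common) == 0:
        raise SeriesError("pulls share no common dates")
    cols = []
    for p in pulls:
        cols.append(p.values[p.start_dates.get_indexer(common)])
    mat = np.column_stack(cols)
    n_missing = np.isnan(mat).sum(axis=1)
    mat = mat[n_missing <= max_missing_pulls]
    mat = mat[~np.isnan(mat).any(axis=1)]
    return PullMatrix(mat, label=pulls[0].label, region=pulls[0].region)


def average_pulls(pulls: list[WeeklySeries], max_missing_pulls: int = 0) -> WeeklySeries:
    """Pointwise mean of aligned pulls (the averaged consensus series).

    A cell is missing in the average if more than ``max_missing_pulls``
    pulls miss it; otherwise it is the mean of the present values.
    """
    if len(pulls) < 2:
        raise ValueError("at least 2 pulls are required")
    common = pulls[0].start_dates
    for p in pulls[1:]:
        common = common.intersection(p.start_dates)
    if len(common) == 0:
        raise SeriesError("pulls share no common dates")
    mat = np.column_stack([p.values[p.start_dates.get_indexer(common)] for p in pulls])
    present = ~np.isnan(mat)
    n_present = present.sum(axis=1)
    ok = (len(pulls) - n_present <= max_missing_pulls) & (n_present > 0)
    mean = np.full(len(common), np.nan)
    mean[ok] = np.nansum(np.where(present, mat, 0.0), axis=1)[ok] / n_present[ok]
    return WeeklySeries(common, mean, label=pulls[0].label, region=pulls[0].region)
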