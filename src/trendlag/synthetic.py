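"""Synthetic search-volume and outcome-count generators.

Every downstream stage (preprocessing, reliability, SARIMA modelling,
prewhitened cross-correlation, grid evaluation) is exercised on data from
this module, because the real inputs — raw Google Trends pulls and national
cause-of-death registers — cannot be redistributed or re-fetched as they
stood.  The generators therefore emulate the relevant structure with known
ground truth:

* weekly search series follow a seasonal ARIMA process, are shifted/scaled
  so the maximum is 100, rounded to integers, and carry injected missing
  runs and innovative (IO) / additive (AO) outlier events;
* repeated "pulls" of the same term are noisy re-normalized replicates of
  one latent series, so pull-to-pull agreement (ICC) is controllable;
* monthly outcome counts share the explanatory series' ARMA filter, with a
  cross-lagged transfer effect of specified lag and magnitude injected at
  the innovation level.  Under this shared-filter construction the
  population prewhitened cross-correlation equals ``target_ccf`` at exactly
  the specified lag and zero elsewhere, which makes recovery tests exact in
  expectation.

All functions are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .series import MonthlySeries, WeeklySeries

__all__ = [
    "GenSpec",
    "TransferSpec",
    "LatentMonthly",
    "generate_search_series",
    "generate_pulls",
    "generate_monthly_volume",
    "generate_outcome_series",
    "generate_pair",
]

#: Warm-up length discarded before the observation window so that filter
#: start-up transients and integration constants have washed out.
_BURN = 240
#: Extra innovations generated beyond the window so positive-lag transfer
#: effects have future innovations to draw on.
_PAD = 8

OutlierType = Literal["IO", "AO"]


class ConstraintError(ValueError):
    """Missingness constraints cannot be satisfied."""


def _ar_poly(coefs: Sequence[float], s: int = 1) -> np.ndarray:
    """phi(B^s) as ascending-power coefficients: 1 - c1 B^s - c2 B^2s - ..."""
    poly = np.zeros(len(coefs) * s + 1)
    poly[0] = 1.0
    for i, c in enumerate(coefs, start=1):
        poly[i * s] = -c
    return poly


def _ma_poly(coefs: Sequence[float], s: int = 1) -> np.ndarray:
    """theta(B^s): 1 + c1 B^s + c2 B^2s + ..."""
    poly = np.zeros(len(coefs) * s + 1)
    poly[0] = 1.0
    for i, c in enumerate(coefs, start=1):
        poly[i * s] = c
    return poly


def _check_roots(poly: np.ndarray, what: str) -> None:
    if len(poly) <= 1:
        return
    roots = np.roots(poly[::-1])
    if roots.size and np.min(np.abs(roots)) <= 1.0 + 1e-8:
        raise ValueError(f"{what} polynomial has roots on or inside the unit circle")


@dataclass(frozen=True)
class GenSpec:
    """Generative seasonal-ARIMA specification for one search-volume series.

    ``arima_orders`` is the (p, d, q, P, D, Q) tuple; ``season_length`` the
    seasonal period (12 for monthly seasonality, 52 for weekly).  Outlier
    events are (position, "IO"|"AO", magnitude) with magnitude in units of
    the innovation standard deviation; AO contaminates one observation, IO
    one innovation so the shock propagates through the dynamics.
    """

    arima_orders: tuple[int, int, int, int, int, int] = (1, 0, 0, 0, 0, 0)
    season_length: int = 12
    ar: tuple[float, ...] = (0.5,)
    ma: tuple[float, ...] = ()
    seasonal_ar: tuple[float, ...] = ()
    seasonal_ma: tuple[float, ...] = ()
    innovation_sd: float = 1.0
    level: float = 50.0
    n_weeks: int = 200
    missing_fraction: float = 0.0
    max_missing_run: int = 4
    outlier_events: tuple[tuple[int, OutlierType, float], ...] = ()
    pull_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p, d, q, P, D, Q = self.arima_orders
        if min(self.arima_orders) < 0 or self.season_length < 1:
            raise ValueError("orders must be non-negative, season length positive")
        if (len(self.ar), len(self.ma)) != (p, q) or (len(self.seasonal_ar), len(self.seasonal_ma)) != (P, Q):
            raise ValueError("coefficient vector lengths must match the stated orders")
        if self.innovation_sd <= 0 or self.pull_noise_sd < 0:
            raise ValueError("innovation_sd must be positive, pull_noise_sd non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_weeks < 1 or self.max_missing_run < 1:
            raise ValueError("n_weeks and max_missing_run must be positive")
        _check_roots(_ar_poly(self.ar), "AR")
        _check_roots(_ar_poly(self.seasonal_ar, self.season_length), "seasonal AR")
        _check_roots(_ma_poly(self.ma), "MA")
        _check_roots(_ma_poly(self.seasonal_ma, self.season_length), "seasonal MA")
        n_miss = round(self.missing_fraction * self.n_weeks)
        n_present = self.n_weeks - n_miss
        if n_miss > self.max_missing_run * (n_present + 1):
            raise ConstraintError(
                "missing_fraction and max_missing_run jointly unsatisfiable for n_weeks"
            )

    @property
    def ar_full(self) -> np.ndarray:
        """Stationary AR operator: phi(B) * PHI(B^s), ascending powers of B."""
        return np.convolve(_ar_poly(self.ar), _ar_poly(self.seasonal_ar, self.season_length))

    @property
    def ma_full(self) -> np.ndarray:
        return np.convolve(_ma_poly(self.ma), _ma_poly(self.seasonal_ma, self.season_length))


@dataclass(frozen=True)
class TransferSpec:
    """Cross-lagged transfer effect from search volumes onto outcome counts.

    A negative ``lag`` means the search series leads the outcome: the
    outcome innovation at month *m* loads on the search innovation at month
    *m + lag* (i.e. ``|lag|`` months earlier).
    """

    target_ccf: float = 0.0
    lag: int = 0
    outcome_mean_level: float = 100.0
    outcome_scale: float = 10.0
    noise_model: Literal["gaussian", "poisson"] = "gaussian"

    def __post_init__(self) -> None:
        if not abs(self.target_ccf) < 1:
            raise ValueError("|target_ccf| must be < 1")
        if not -3 <= self.lag <= 3:
            raise ValueError("lag must lie within the analysis window -3..+3")
        if self.outcome_mean_level <= 0:
            raise ValueError("outcome_mean_level must be positive")


# ---------------------------------------------------------------------------
# Core simulator
# ---------------------------------------------------------------------------

def _simulate(spec: GenSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` observations of the spec's seasonal ARIMA process.

    Returns ``(window, innovations)`` where ``window`` has length ``n`` and
    ``innovations`` is the full innovation sequence of length
    ``_BURN + n + _PAD`` (window month ``i`` corresponds to innovation index
    ``_BURN + i``).  IO outlier events are applied to the innovations here;
    AO events are handled by the callers on the observation scale.
    """
    _, d, _, _, D, _ = spec.arima_orders
    s = spec.season_length
    total = _BURN + n + _PAD
    e = rng.normal(0.0, spec.innovation_sd, size=total)
    for pos, kind, mag in spec.outlier_events:
        if not 0 <= pos < n:
            raise ValueError("outlier position outside the series")
        if kind == "IO":
            e[_BURN + pos] += mag * spec.innovation_sd
    x = lfilter(spec.ma_full, spec.ar_full, e)
    for _ in range(D):
        for t in range(s, total):
            x[t] += x[t - s]
    for _ in range(d):
        x = np.cumsum(x)
    return x[_BURN:_BURN + n], e


def _inject_missing(
    n: int, fraction: float, max_run: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean missing mask with runs never exceeding ``max_run``."""
    target = round(fraction * n)
    mask = np.zeros(n, dtype=bool)
    placed = 0
    for _ in range(50):  # rescans; feasibility was checked at spec creation
        if placed >= target:
            break
        for idx in rng.permutation(n):
            if placed >= target or mask[idx]:
                continue
            mask[idx] = True
            lo = idx
            while lo > 0 and mask[lo - 1]:
                lo -= 1
            hi = idx
            while hi < n - 1 and mask[hi + 1]:
                hi += 1
            if hi - lo + 1 > max_run:
                mask[idx] = False
            else:
                placed += 1
    if placed < target:
        raise ConstraintError("could not place the requested missing values")
    return mask


def _normalize(x: np.ndarray) -> np.ndarray:
    """Shift to a zero minimum, scale the maximum to 100, round to integers."""
    y = x - x.min()
    top = y.max()
    if top == 0:
        return np.zeros_like(y)
    return np.round(y * (100.0 / top))


_DEFAULT_WEEK_START = pd.Timestamp("2004-01-04")  # a Sunday, export convention


def generate_search_series(spec: GenSpec, start: pd.Timestamp | None = None) -> WeeklySeries:
    """Generate one weekly normalized search-volume series.

    The latent seasonal-ARIMA path (with IO events in its innovations and AO
    events added on the observation scale) is shifted and scaled so its
    maximum equals 100, rounded to integers, and missing weeks are injected
    per the spec.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    x, _ = _simulate(spec, spec.n_weeks, rng)
    for pos, kind, mag in spec.outlier_events:
        if kind == "AO":
            x[pos] += mag * spec.innovation_sd
    values = _normalize(x)
    mask = _inject_missing(spec.n_weeks, spec.missing_fraction, spec.max_missing_run, rng)
    values = np.where(mask, np.nan, values)
    start = _DEFAULT_WEEK_START if start is None else start
    dates = pd.date_range(start, periods=spec.n_weeks, freq="7D")
    return WeeklySeries(dates, values, label="synthetic", region="synthetic")


def generate_pulls(
    spec: GenSpec, k: int, start: pd.Timestamp | None = None
) -> list[WeeklySeries]:
    """Generate ``k`` noisy re-normalized replicates ("pulls") of one series.

    Independent Gaussian noise of sd ``spec.pull_noise_sd`` is added to the
    shared latent series before each pull's own 0–100 normalization, so
    expected pairwise agreement decreases monotonically in the noise level.
    """
    if k < 2:
        raise ValueError("at least 2 pulls are required")
    rng = np.random.default_rng(spec.seed)
    x, _ = _simulate(spec, spec.n_weeks, rng)
    for pos, kind, mag in spec.outlier_events:
        if kind == "AO":
            x[pos] += mag * spec.innovation_sd
    mask = _inject_missing(spec.n_weeks, spec.missing_fraction, spec.max_missing_run, rng)
    start = _DEFAULT_WEEK_START if start is None else start
    dates = pd.date_range(start, periods=spec.n_weeks, freq="7D")
    pulls = []
    for j in range(k):
        noisy = x + rng.normal(0.0, spec.pull_noise_sd, size=spec.n_weeks)
        values = np.where(mask, np.nan, _normalize(noisy))
        pulls.append(WeeklySeries(dates, values, label="synthetic", region=f"pull{j}"))
    return pulls


# ---------------------------------------------------------------------------
# Monthly volumes and transfer-linked outcomes
# ---------------------------------------------------------------------------

class LatentMonthly(NamedTuple):
    """A monthly explanatory series together with its generative innovations.

    ``offset`` is the index into ``innovations`` of the first window month.
    """

    series: MonthlySeries
    innovations: np.ndarray
    offset: int


_DEFAULT_MONTH_START = pd.Period("2004-01", freq="M")


def generate_monthly_volume(
    spec: GenSpec,
    n_months: int,
    start: pd.Period | None = None,
    label: str = "synthetic",
    region: str = "synthetic",
) -> LatentMonthly:
    """Generate a monthly explanatory series directly on the monthly grid.

    Values are left continuous (they stand for already-aggregated monthly
    search volumes); ``spec.level`` sets the mean level.
    """
    rng = np.random.default_rng(spec.seed)
    x, e = _simulate(spec, n_months, rng)
    for pos, kind, mag in spec.outlier_events:
        if kind == "AO":
            x[pos] += mag * spec.innovation_sd
    start = _DEFAULT_MONTH_START if start is None else start
    months = pd.period_range(start, periods=n_months, freq="M")
    series = MonthlySeries(months, x + spec.level, label=label, region=region)
    return LatentMonthly(series, e, _BURN)


def generate_outcome_series(
    x: LatentMonthly,
    spec: GenSpec,
    transfer: TransferSpec,
    seed: int,
    label: str = "outcome",
    region: str = "synthetic",
) -> MonthlySeries:
    """Generate a monthly outcome-count series with a known transfer effect.

    The outcome innovation at month *m* is
    ``target_ccf * e_x[m + lag] + sqrt(1 - target_ccf^2) * eta_m`` with
    ``eta`` independent noise of the same sd, recolored through the same
    ARMA/integration filter as the explanatory series, then mapped to counts
    (gaussian: affine around ``outcome_mean_level``; poisson: log-link).
    The population prewhitened CCF is ``target_ccf`` at exactly ``lag``
    (negative lag = search series leads the outcome) and zero elsewhere.
    """
    n = x.series.n_months
    e = x.innovations
    lag = transfer.lag
    if len(e) < x.offset + n + max(0, lag):
        raise ValueError("explanatory innovations do not cover the outcome span plus lag")
    rng = np.random.default_rng(seed)
    rho = transfer.target_ccf
    a = max(0, -lag)  # first full index with a valid shifted partner
    m = len(e) - a - max(0, lag)
    eta = rng.normal(0.0, spec.innovation_sd, size=m)
    u = rho * e[a + lag:a + lag + m] + np.sqrt(1.0 - rho**2) * eta

    _, d, _, _, D, _ = spec.arima_orders
    s = spec.season_length
    y = lfilter(spec.ma_full, spec.ar_full, u)
    for _ in range(D):
        for t in range(s, m):
            y[t] += y[t - s]
    for _ in range(d):
        y = np.cumsum(y)
    window = y[x.offset - a:x.offset - a + n]

    if transfer.noise_model == "gaussian":
        counts = transfer.outcome_mean_level + transfer.outcome_scale * (
            window / spec.innovation_sd
        )
    else:  # poisson log-link; mild log-scale variation keeps counts realistic
        g = 0.1 * window / max(np.std(window), 1e-12)
        counts = rng.poisson(transfer.outcome_mean_level * np.exp(g - np.var(g) / 2.0))
    return MonthlySeries(x.series.months, counts.astype(float), label=label, region=region)


def generate_pair(
    spec: GenSpec,
    transfer: TransferSpec,
    n_months: int,
    seed: int,
) -> tuple[MonthlySeries, MonthlySeries]:
    """Convenience: one explanatory/outcome monthly pair with known transfer.

    Seeds for the two series are derived from ``seed`` so pairs with
    different seeds are mutually independent.
    """
    from dataclasses import replace

    x = generate_monthly_volume(replace(spec, seed=seed * 2 + 1), n_months)
    y = generate_outcome_series(x, spec, transfer, seed=seed * 2 + 2)
    return x.series, y
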