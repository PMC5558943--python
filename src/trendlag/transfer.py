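"""Prewhitening and cross-correlation of explanatory/dependent series pairs.

The explanatory series (monthly search volumes) is filtered by its own
fitted (S)ARIMA model to innovations, and the *identical* filter — same
differencing, same ARMA coefficients, frozen, no re-estimation — is applied
to the dependent series (monthly suicide counts).  Cross-correlations of
the filtered pair are then free of the autocorrelation and trend the two
raw series share, which is what guards against spurious associations.

Lag sign convention (pinned, because library conventions differ): a
NEGATIVE lag pairs the explanatory series at month *t* with the dependent
series ``|k|`` months LATER — significant negative-lag correlations mean
searching precedes the outcome ("x leads y").  Positive lags mean the
outcome precedes the searching; lag 0 is temporally ambiguous.

Significance bands use the standard large-sample null sd of a sample
cross-correlation, ``z_{1-alpha/2} / sqrt(n_pairs)``, with the pair count
``n - |k|`` specific to each lag (no single-n shortcut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arima import ArimaSpec, FittedModel
from .series import MonthlySeries, SeriesError

__all__ = ["PrewhitenedPair", "CcfResult", "prewhiten", "ccf", "classify_lags"]

MIN_OVERLAP_MONTHS = 36


@dataclass(frozen=True)
class PrewhitenedPair:
    """Innovations of x and the identically filtered y, on a common span."""

    x_innovations: np.ndarray
    y_filtered: np.ndarray
    model_used: ArimaSpec
    x_label: str = ""
    y_label: str = ""


@dataclass(frozen=True)
class CcfResult:
    """Cross-correlations at lags -max_lag..+max_lag with per-lag bands."""

    lags: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray
    band: np.ndarray
    significant: np.ndarray
    x_label: str = ""
    y_label: str = ""

    def at(self, lag: int) -> float:
        return float(self.r[int(np.flatnonzero(self.lags == lag)[0])])

    def peak_lag(self) -> int:
        return int(self.lags[int(np.nanargmax(np.abs(self.r)))])


def _difference(x: np.ndarray, spec: ArimaSpec) -> np.ndarray:
    for _ in range(spec.d):
        x = np.diff(x)
    for _ in range(spec.D):
        x = x[spec.s:] - x[:-spec.s]
    return x


def _innovations(x: np.ndarray, model: FittedModel) -> np.ndarray:
    """Difference, demean, and whiten one series with the frozen ARMA filter.

    Whitening uses the exact finite-sample (Kalman) innovations of the
    stationary ARMA model rather than a zero-initialized recursion, so no
    start-up observations need to be discarded and the innovations are
    variance-equalized from the first point.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    spec = model.spec
    z = _difference(np.asarray(x, dtype=float), spec)
    z = z - z.mean()
    if spec.n_arma_params == 0:
        return z
    mod = SARIMAX(
        z,
        order=(spec.p, 0, spec.q),
        seasonal_order=(spec.P, 0, spec.Q, spec.s),
        trend="n",
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    values = {
        **{f"ar.L{i}": c for i, c in enumerate(model.ar, 1)},
        **{f"ma.L{i}": c for i, c in enumerate(model.ma, 1)},
        **{f"ar.S.L{i * spec.s}": c for i, c in enumerate(model.seasonal_ar, 1)},
        **{f"ma.S.L{i * spec.s}": c for i, c in enumerate(model.seasonal_ma, 1)},
        "sigma2": model.sigma2,
    }
    params = np.array([values[name] for name in mod.param_names])
    res = mod.filter(params)
    return np.asarray(res.standardized_forecasts_error[0], dtype=float)


def prewhiten(x: MonthlySeries, y: MonthlySeries, model: FittedModel) -> PrewhitenedPair:
    """Filter x by its own fitted model and y by the identical frozen filter.

    The fitted contribution of x's outlier regressors is removed from x
    before filtering (outliers are interventions on the search series, not
    on the outcome, so no regressors are applied to y).  Whitening uses the
    exact finite-sample innovations of the frozen model, so the filtered
    pair spans the whole differenced overlap with no start-up truncation.
    """
    x_al, y_al = x.align(y)
    if x_al.n_months < MIN_OVERLAP_MONTHS:
        raise SeriesError(
            f"series overlap on {x_al.n_months} months; at least {MIN_OVERLAP_MONTHS} required"
        )
    x_values = x_al.values.copy()
    if model.exog is not None:
        effect = model.outlier_effect()
        idx = model.series.months.get_indexer(x_al.months)
        if (idx < 0).any():
            raise SeriesError("model was not fitted on the explanatory series' span")
        x_values -= effect[idx]
    e_x = _innovations(x_values, model)
    e_y = _innovations(y_al.values, model)
    return PrewhitenedPair(
        x_innovations=e_x,
        y_filtered=e_y,
        model_used=model.spec,
        x_label=x.label,
        y_label=y.label,
    )


def ccf(pair: PrewhitenedPair, max_lag: int = 3, alpha: float = 0.05) -> CcfResult:
    """Pearson cross-correlations of the prewhitened pair at each lag.

    For lag ``k < 0`` the pairs are ``(x_t, y_{t+|k|})``; for ``k > 0``
    they are ``(x_{t+k}, y_t)``.  A lag with degenerate variance yields
    ``r = NaN`` and is never flagged significant.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    x, y = pair.x_innovations, pair.y_filtered
    n = len(x)
    if n <= max_lag + 2:
        raise SeriesError("series too short for the requested lag window")
    lags = np.arange(-max_lag, max_lag + 1)
    z = stats.norm.ppf(1 - alpha / 2)
    r = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    for i, k in enumerate(lags):
        if k <= 0:
            a, b = x[: n + k], y[-k:]
        else:
            a, b = x[k:], y[: n - k]
        n_pairs[i] = len(a)
        if np.std(a) == 0 or np.std(b) == 0:
            r[i] = np.nan
        else:
            r[i] = float(np.corrcoef(a, b)[0, 1])
    band = z / np.sqrt(n_pairs)
    significant = np.abs(np.nan_to_num(r)) > band
    return CcfResult(lags, r, n_pairs, band, significant, pair.x_label, pair.y_label)


def classify_lags(result: CcfResult) -> list[dict]:
    """Lead/lag interpretation of each lag of a CCF result.

    Significant negative lags are ``x_leads_y`` (searching precedes the
    outcome), positive lags ``y_leads_x``, lag 0 ``coincident``;
    non-significant lags are ``null``.
    """
    records = []
    for lag, r, sig in zip(result.lags, result.r, result.significant):
        if not sig:
            label = "null"
        elif lag < 0:
            label = "x_leads_y"
        elif lag > 0:
            label = "y_leads_x"
        else:
            label = "coincident"
        records.append(
            {
                "lag": int(lag),
                "r": float(r) if np.isfinite(r) else None,
                "classification": label,
                "sign": int(np.sign(r)) if sig and np.isfinite(r) else 0,
            }
        )
    return records
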