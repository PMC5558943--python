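"""Term-by-stratum evaluation grid, idealized patterns, and summaries.

The evaluation design crosses retained search terms with outcome strata —
total suicides, younger (<40 years) and older (40+) individuals, older men
and older women, plus overall male/female rates for the two
overdose-method terms, since poisoning is a frequent suicide method among
women — at lags -3..+3.  Each cell runs the full pipeline: model selection
on the term series, prewhitening, cross-correlation, lead/lag
classification.

Idealized patterns encode what cross-correlations would look like if
search volumes genuinely forecast suicide rates: largest at lag 0
(magnitude .40, or .50 for the younger, older-men, and overdose-women
strata), shrinking by .10 with each preceding month, positive for
pro-suicide terms and *depression*, negative for prevention terms, and
zero at positive lags (the forecasting direction).  The observed share of
significant coefficients is compared against the 5% Type-I-error benchmark
expected under pure chance with uncorrected per-coefficient tests (no
multiplicity correction by default — the benchmark argument depends on
uncorrected tests; a Bonferroni option exists).

``REFERENCE_TERMS`` embeds the reference study catalogue of 29 retained
terms across the USA, Germany, Austria, and Switzerland with their series
lengths (months) and weekly missing fractions, so design arithmetic and
screening-rule checks can be reproduced without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .arima import FitError, GridConfig, select_model
from .series import MonthlySeries, SeriesError
from .transfer import CcfResult, ccf, classify_lags, prewhiten

__all__ = [
    "TermSpec",
    "AnalysisDesign",
    "IdealPattern",
    "GridCell",
    "SummaryReport",
    "REFERENCE_TERMS",
    "reference_design",
    "short_series",
    "build_ideal",
    "count_grid",
    "run_grid",
    "summarize",
    "export_heatmap",
    "read_heatmap",
    "simulate_null_rate",
    "simulate_injection_recovery",
    "simulate_store",
]

TermClass = Literal["pro_suicide", "prevention", "depression"]

DEFAULT_STRATA = ("total", "younger", "older", "older_men", "older_women")

#: Lag-0 magnitude of the idealized pattern per stratum.
IDEAL_MAGNITUDE = {
    "total": 0.40,
    "younger": 0.50,
    "older": 0.40,
    "older_men": 0.50,
    "older_women": 0.40,
    # overall male/female strata only arise for the overdose-method terms
    "men": 0.40,
    "women": 0.50,
}
IDEAL_STEP = 0.10

#: Effect-size bin edges on |r| (lower-inclusive): negligible / small / medium / large.
BIN_EDGES = (0.10, 0.30, 0.50)


@dataclass(frozen=True)
class TermSpec:
    label: str
    term_class: TermClass
    region: str
    n_months: int = 0
    missing_fraction: float = 0.0


# Reference catalogue: 29 retained terms with series length in months and the
# weekly missing-value fraction of each raw series.
REFERENCE_TERMS: tuple[TermSpec, ...] = (
    TermSpec("suicide", "pro_suicide", "USA", 84, 0.0),
    TermSpec("depression", "depression", "USA", 84, 0.0),
    TermSpec("how to kill yourself", "pro_suicide", "USA", 72, 0.0),
    TermSpec('"how to kill yourself"', "pro_suicide", "USA", 68, 0.0169),
    TermSpec("how to overdose", "pro_suicide", "USA", 61, 0.0564),
    TermSpec('"how to overdose"', "pro_suicide", "USA", 37, 0.0),
    TermSpec("online suicide", "pro_suicide", "USA", 47, 0.0293),
    TermSpec("painless suicide", "pro_suicide", "USA", 83, 0.0138),
    TermSpec('"painless suicide"', "pro_suicide", "USA", 44, 0.0573),
    TermSpec('"suicide chat"', "pro_suicide", "USA", 49, 0.0),
    TermSpec("suicide methods", "pro_suicide", "USA", 83, 0.0),
    TermSpec('"suicide methods"', "pro_suicide", "USA", 76, 0.0574),
    TermSpec("suicide help", "prevention", "USA", 83, 0.0137),
    TermSpec('"suicide help"', "prevention", "USA", 62, 0.0519),
    TermSpec("suicide hotline", "prevention", "USA", 71, 0.0),
    TermSpec('"suicide hotline"', "prevention", "USA", 68, 0.0304),
    TermSpec("suicide prevention", "prevention", "USA", 84, 0.0),
    TermSpec('"suicide prevention"', "prevention", "USA", 84, 0.0),
    TermSpec('"suicide survivors"', "prevention", "USA", 62, 0.0),
    TermSpec("Suizid", "pro_suicide", "Germany", 108, 0.0),
    TermSpec("Selbstmord", "pro_suicide", "Germany", 108, 0.0),
    TermSpec("Depressionen", "depression", "Germany", 108, 0.0),
    TermSpec("Freitod", "pro_suicide", "Germany", 38, 0.0),
    TermSpec("Selbstmord Forum", "pro_suicide", "Germany", 108, 0.0),
    TermSpec("Suizid", "pro_suicide", "Austria", 37, 0.0494),
    TermSpec("Selbstmord", "pro_suicide", "Austria", 98, 0.0492),
    TermSpec("Depressionen", "depression", "Austria", 75, 0.0214),
    TermSpec("Selbstmord", "pro_suicide", "Switzerland", 48, 0.0239),
    TermSpec("Depressionen", "depression", "Switzerland", 40, 0.0862),
)

#: Terms that additionally get overall male/female strata.
OVERDOSE_TERMS = ("how to overdose", '"how to overdose"')


@dataclass(frozen=True)
class AnalysisDesign:
    """Term list, strata, extra strata, lag window, and test level."""

    terms: tuple[TermSpec, ...]
    strata: tuple[str, ...] = DEFAULT_STRATA
    extra_strata: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    lags: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    alpha: float = 0.05
    age_cut: int = 40

    def cells(self) -> list[tuple[TermSpec, str]]:
        out = []
        for term in self.terms:
            for stratum in self.strata:
                out.append((term, stratum))
            for stratum in self.extra_strata.get(term.label, ()):
                out.append((term, stratum))
        return out


def reference_design() -> AnalysisDesign:
    """The reference evaluation design: 29 terms, 5 strata, overdose extras."""
    return AnalysisDesign(
        terms=REFERENCE_TERMS,
        extra_strata={label: ("men", "women") for label in OVERDOSE_TERMS},
    )


def short_series(threshold: int = 50, terms: Iterable[TermSpec] = REFERENCE_TERMS) -> list[TermSpec]:
    """Terms whose series length falls below ``threshold`` data points."""
    return [t for t in terms if t.n_months < threshold]


@dataclass(frozen=True)
class IdealPattern:
    """Expected cross-correlations at lags -3..0 if forecasting worked."""

    expected_r: Mapping[int, float]
    expected_sign: int
    zero_at_positive_lags: bool = True


def build_ideal(term_class: TermClass, stratum: str) -> IdealPattern:
    """Idealized pattern for one term class and outcome stratum.

    Magnitude at lag 0 is stratum-specific (see :data:`IDEAL_MAGNITUDE`),
    shrinking by .10 per preceding lag; the sign is positive for
    pro-suicide terms and *depression*, negative for prevention terms.
    """
    if stratum not in IDEAL_MAGNITUDE:
        raise ValueError(f"unknown stratum: {stratum!r}")
    if term_class not in ("pro_suicide", "prevention", "depression"):
        raise ValueError(f"unknown term class: {term_class!r}")
    sign = -1 if term_class == "prevention" else +1
    base = IDEAL_MAGNITUDE[stratum]
    expected = {lag: sign * (base + IDEAL_STEP * lag) for lag in (-3, -2, -1, 0)}
    return IdealPattern(expected_r=expected, expected_sign=sign)


def count_grid(design: AnalysisDesign) -> int:
    """Total number of cross-correlation coefficients in the design."""
    return len(design.cells()) * len(design.lags)


@dataclass
class GridCell:
    term: TermSpec
    stratum: str
    result: CcfResult | None
    ideal: IdealPattern
    classification: list[dict] | None = None
    model_label: str = ""
    error: str | None = None


@dataclass(frozen=True)
class SeriesStore:
    """Prepared monthly series: term volumes and per-stratum outcome counts.

    ``volumes`` is keyed by (region, term label); ``outcomes`` by
    (region, stratum).
    """

    volumes: Mapping[tuple[str, str], MonthlySeries]
    outcomes: Mapping[tuple[str, str], MonthlySeries]


def run_grid(
    store: SeriesStore,
    design: AnalysisDesign,
    grid: GridConfig | None = None,
    model_selector: Callable[[MonthlySeries], object] | None = None,
) -> list[GridCell]:
    """Run the full pipeline for every (term, stratum) cell.

    Each term's explanatory model is selected once and reused across its
    strata.  Failures are recorded per cell, never fatal, so a single
    ill-behaved series cannot sink the grid.  ``model_selector`` overrides
    grid-search selection (e.g. to supply known orders in simulations).
    """
    selector = model_selector or (lambda s: select_model(s, grid))
    max_lag = max(abs(l) for l in design.lags)
    cells: list[GridCell] = []
    for term in design.terms:
        strata = list(design.strata) + list(design.extra_strata.get(term.label, ()))
        x = store.volumes.get((term.region, term.label))
        model = None
        model_error = None
        if x is None:
            model_error = "missing volume series"
        else:
            try:
                model = selector(x)
            except (FitError, SeriesError) as exc:
                model_error = f"model selection failed: {exc}"
        for stratum in strata:
            ideal = build_ideal(term.term_class, stratum)
            if model_error is not None:
                cells.append(GridCell(term, stratum, None, ideal, error=model_error))
                continue
            y = store.outcomes.get((term.region, stratum))
            if y is None:
                cells.append(GridCell(term, stratum, None, ideal, error="missing outcome series"))
                continue
            try:
                pair = prewhiten(x, y, model)
                result = ccf(pair, max_lag=max_lag, alpha=design.alpha)
            except (SeriesError, ValueError) as exc:
                cells.append(GridCell(term, stratum, None, ideal, error=str(exc)))
                continue
            cells.append(
                GridCell(
                    term,
                    stratum,
                    result,
                    ideal,
                    classification=classify_lags(result),
                    model_label=model.spec.label(),
                )
            )
    return cells


def _concordance(cell: GridCell) -> float | None:
    """Sign-weighted agreement of the observed significant lags with the ideal.

    Each significant lag scores +1 if it sits at a non-positive lag with
    the expected sign, -1 if its sign is wrong or it sits at a positive lag
    (discordant with forecasting); the cell score is the mean, in [-1, 1].
    Cells with no significant lag score 0.
    """
    if cell.result is None:
        return None
    scores = []
    for lag, r, sig in zip(cell.result.lags, cell.result.r, cell.result.significant):
        if not sig or not np.isfinite(r):
            continue
        if lag > 0:
            scores.append(-1.0)
        else:
            scores.append(1.0 if np.sign(r) == cell.ideal.expected_sign else -1.0)
    return float(np.mean(scores)) if scores else 0.0


@dataclass(frozen=True)
class SummaryReport:
    n_coefficients: int
    pct_significant: float
    bin_counts: tuple[int, int, int, int]  # large, medium, small, negligible
    median_abs_r: float
    iqr_abs_r: tuple[float, float]
    per_region_pct_significant: Mapping[str, float]
    concordance: Mapping[tuple[str, str, str], float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_coefficients": self.n_coefficients,
            "pct_significant": self.pct_significant,
            "bin_counts": {
                "large": self.bin_counts[0],
                "medium": self.bin_counts[1],
                "small": self.bin_counts[2],
                "negligible": self.bin_counts[3],
            },
            "median_abs_r": self.median_abs_r,
            "iqr_abs_r": list(self.iqr_abs_r),
            "per_region_pct_significant": dict(self.per_region_pct_significant),
            "concordance": {"|".join(k): v for k, v in self.concordance.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def summarize(cells: list[GridCell]) -> SummaryReport:
    """Pool all coefficients: effect-size bins, significance rate, concordance.

    Bins follow the printed boundaries, lower-inclusive: large |r| >= .50,
    medium .30 <= |r| < .50, small .10 <= |r| < .30, else negligible.
    """
    if not cells:
        raise ValueError("no cells to summarize")
    rows = []
    for cell in cells:
        if cell.result is None:
            continue
        for r, sig in zip(cell.result.r, cell.result.significant):
            if np.isfinite(r):
                rows.append((cell.term.region, abs(r), bool(sig)))
    if not rows:
        raise ValueError("no finite coefficients to summarize")
    regions = np.array([r for r, _, _ in rows])
    abs_r = np.array([a for _, a, _ in rows])
    sig = np.array([s for _, _, s in rows])
    large = int(np.sum(abs_r >= BIN_EDGES[2]))
    medium = int(np.sum((abs_r >= BIN_EDGES[1]) & (abs_r < BIN_EDGES[2])))
    small = int(np.sum((abs_r >= BIN_EDGES[0]) & (abs_r < BIN_EDGES[1])))
    negligible = len(abs_r) - large - medium - small
    per_region = {
        region: float(100.0 * sig[regions == region].mean())
        for region in sorted(set(regions))
    }
    concordance = {}
    for cell in cells:
        score = _concordance(cell)
        if score is not None:
            concordance[(cell.term.region, cell.term.label, cell.stratum)] = score
    lo, hi = np.percentile(abs_r, [25, 75])
    return SummaryReport(
        n_coefficients=len(abs_r),
        pct_significant=float(100.0 * sig.mean()),
        bin_counts=(large, medium, small, negligible),
        median_abs_r=float(np.median(abs_r)),
        iqr_abs_r=(float(lo), float(hi)),
        per_region_pct_significant=per_region,
        concordance=concordance,
    )


def export_heatmap(cells: list[GridCell], path: str | Path | None = None) -> pd.DataFrame:
    """Long-format heat-map table: one row per (region, term, stratum, lag).

    This is the data layer of the heat-map figures; rendering is left to
    the caller.  Ordering is deterministic (input cell order, then lag).
    """
    rows = []
    for cell in cells:
        if cell.result is None:
            continue
        for lag, r, band, sig in zip(
            cell.result.lags, cell.result.r, cell.result.band, cell.result.significant
        ):
            rows.append(
                {
                    "region": cell.term.region,
                    "term": cell.term.label,
                    "term_class": cell.term.term_class,
                    "stratum": cell.stratum,
                    "lag": int(lag),
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "band": float(band),
                    "significant": bool(sig),
                    "ideal_r": cell.ideal.expected_r.get(int(lag), 0.0),
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_heatmap(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


#: Generative structure used for calibration studies: seasonal AR(1) with a
#: seasonal moving-average component, the modal structure of monthly
#: search-volume series.
CALIBRATION_SPEC_KWARGS = dict(
    arima_orders=(1, 0, 0, 0, 1, 1), ar=(0.5,), seasonal_ma=(-0.6,), season_length=12
)


def _calibration_spec():
    from .synthetic import GenSpec

    return GenSpec(**CALIBRATION_SPEC_KWARGS)


def simulate_null_rate(
    n_pairs: int = 500,
    n_months: int = 84,
    seed: int = 0,
    alpha: float = 0.05,
    max_lag: int = 3,
) -> tuple[float, int]:
    """Type-I-error calibration of the full prewhitened-CCF pipeline.

    Generates ``n_pairs`` independent explanatory/outcome pairs with no
    transfer effect, fits the explanatory model (true orders supplied),
    prewhitens, and pools significance flags over all lags.  Returns the
    percentage of significant coefficients and the pooled coefficient
    count; under correct calibration the percentage is close to
    ``100 * alpha``.
    """
    from .arima import ArimaSpec, FitError, fit
    from .synthetic import TransferSpec, generate_pair

    gen = _calibration_spec()
    orders = ArimaSpec(*gen.arima_orders[:3], *gen.arima_orders[3:], gen.season_length)
    pair_seeds = np.random.default_rng(seed).integers(0, 2**30, size=n_pairs)
    n_sig = 0
    n_total = 0
    for pair_seed in pair_seeds:
        x, y = generate_pair(gen, TransferSpec(target_ccf=0.0), n_months, seed=int(pair_seed))
        try:
            model = fit(x, orders)
        except FitError:
            continue
        result = ccf(prewhiten(x, y, model), max_lag=max_lag, alpha=alpha)
        n_sig += int(result.significant.sum())
        n_total += len(result.lags)
    return 100.0 * n_sig / n_total, n_total


def simulate_injection_recovery(
    target_ccf: float = 0.5,
    lag: int = -2,
    n_runs: int = 200,
    n_months: int = 84,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Transfer-effect recovery under known injection.

    Returns the mean estimated cross-correlation at the injected lag, the
    share of runs whose CCF peak sits exactly at that lag, and the share of
    runs where the coefficient at that lag exceeds its significance band
    (power).
    """
    from .arima import ArimaSpec, FitError, fit
    from .synthetic import TransferSpec, generate_pair

    gen = _calibration_spec()
    orders = ArimaSpec(*gen.arima_orders[:3], *gen.arima_orders[3:], gen.season_length)
    run_seeds = np.random.default_rng(seed).integers(0, 2**30, size=n_runs)
    rs, peaks, hits = [], 0, 0
    for run_seed in run_seeds:
        x, y = generate_pair(
            gen, TransferSpec(target_ccf=target_ccf, lag=lag), n_months, seed=int(run_seed)
        )
        try:
            model = fit(x, orders)
        except FitError:
            continue
        result = ccf(prewhiten(x, y, model), alpha=alpha)
        rs.append(result.at(lag))
        peaks += result.peak_lag() == lag
        hits += bool(result.significant[int(np.flatnonzero(result.lags == lag)[0])])
    n = len(rs)
    return {
        "mean_r": float(np.mean(rs)),
        "peak_rate": peaks / n,
        "power": hits / n,
        "n_runs": n,
    }


def simulate_store(
    design: AnalysisDesign,
    seed: int,
    n_months: int = 84,
    gen_spec: "GenSpec | None" = None,
    injected: Mapping[tuple[str, str], tuple[str, "TransferSpec"]] | None = None,
) -> SeriesStore:
    """Build a complete synthetic store matching a design.

    Every term gets an independent monthly volume series from ``gen_spec``
    (default: the seasonal AR(1) x seasonal-MA structure typical of search
    volumes).  Outcome strata are independent null series unless
    ``injected`` maps a (region, stratum) to a source term label and a
    :class:`~trendlag.synthetic.TransferSpec`, in which case that outcome
    carries the specified cross-lagged transfer effect from that term's
    innovations.  Deterministic given ``seed``.
    """
    from .synthetic import GenSpec, TransferSpec, generate_monthly_volume, generate_outcome_series

    if gen_spec is None:
        gen_spec = GenSpec(
            arima_orders=(1, 0, 0, 0, 1, 1),
            ar=(0.5,),
            seasonal_ma=(-0.6,),
            season_length=12,
        )
    injected = injected or {}
    rng = np.random.default_rng(seed)
    volumes: dict[tuple[str, str], MonthlySeries] = {}
    latents: dict[tuple[str, str], object] = {}
    for term in design.terms:
        sub = int(rng.integers(0, 2**31 - 1))
        latent = generate_monthly_volume(
            replace(gen_spec, seed=sub), n_months, label=term.label, region=term.region
        )
        latents[(term.region, term.label)] = latent
        volumes[(term.region, term.label)] = latent.series
    outcomes: dict[tuple[str, str], MonthlySeries] = {}
    keys = sorted(
        {(t.region, s) for t in design.terms for s in design.strata}
        | {(t.region, s) for t in design.terms for s in design.extra_strata.get(t.label, ())}
    )
    for region, stratum in keys:
        sub = int(rng.integers(0, 2**31 - 1))
        if (region, stratum) in injected:
            source_label, transfer = injected[(region, stratum)]
            latent = latents[(region, source_label)]
        else:
            transfer = TransferSpec(target_ccf=0.0, lag=0)
            ref = int(rng.integers(0, 2**31 - 1))
            latent = generate_monthly_volume(replace(gen_spec, seed=ref), n_months)
        outcomes[(region, stratum)] = generate_outcome_series(
            latent, gen_spec, transfer, seed=sub, label=stratum, region=region
        )
    return SeriesStore(volumes=volumes, outcomes=outcomes)
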