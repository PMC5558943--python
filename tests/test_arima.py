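"""SARIMA estimation, diagnostics, outlier machinery, and model selection."""

import numpy as np
import pandas as pd
import pytest

import trendlag as tl
from trendlag.arima import ArimaSpec, GridConfig, ljung_box

from helpers import ar1_monthly, make_monthly


SMALL_GRID = GridConfig(
    max_p=1, max_q=1, max_P=0, max_Q=1, max_d=1, max_D=1, max_params=4, with_outliers=False
)


class TestFit:
    def test_white_noise_model_residuals_are_demeaned_series(self, rng):
        y = make_monthly(rng.normal(50, 5, 120))
        model = tl.fit(y, ArimaSpec(0, 0, 0, 0, 0, 0, 12))
        np.testing.assert_allclose(model.residuals, y.values - y.values.mean(), atol=1e-3)
        assert model.diagnostics.whiteness_ok

    def test_ar1_parameter_recovery_within_two_se(self):
        hits = 0
        for seed in range(100):
            series = ar1_monthly(200, seed=seed, phi=0.7)
            model = tl.fit(series, ArimaSpec(1, 0, 0, 0, 0, 0, 12))
            est, se, _ = model.params["ar.L1"]
            hits += abs(est - 0.7) <= 2 * se
        assert hits >= 90  # ~95% nominal, less a small finite-sample bias

    def test_aicc_exceeds_aic(self):
        for seed in range(3):
            series = ar1_monthly(100, seed=seed)
            model = tl.fit(series, ArimaSpec(1, 0, 0, 0, 0, 0, 12))
            assert model.aicc > model.aic

    def test_too_short_series_rejected(self):
        with pytest.raises(tl.series.SeriesError):
            tl.fit(make_monthly(np.arange(30)), ArimaSpec(0, 1, 0, 0, 0, 0, 12))


class TestLjungBox:
    def test_zero_autocorrelation_gives_zero_stat(self):
        # a series whose sample autocorrelations all vanish scores Q = 0, p = 1
        stat, p = ljung_box(np.full(12, 3.14), n_lags=3)
        assert stat == 0.0 and p == 1.0

    def test_matches_direct_formula_oracle(self, rng):
        e = rng.normal(0, 1, 10)
        n = len(e)
        c = e - e.mean()
        denom = c @ c
        r = [float(c[:-j] @ c[j:]) / denom for j in (1, 2, 3)]
        q_oracle = n * (n + 2) * sum(rj**2 / (n - j) for j, rj in zip((1, 2, 3), r))
        stat, _ = ljung_box(e, n_lags=3)
        assert stat == pytest.approx(q_oracle, abs=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.diagnostic import acorr_ljungbox

        e = rng.normal(0, 1, 200)
        stat, p = ljung_box(e, n_lags=12, fitted_params=2)
        ref = acorr_ljungbox(e - e.mean(), lags=[12], model_df=2)
        assert stat == pytest.approx(float(ref["lb_stat"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["lb_pvalue"].iloc[0]), abs=1e-8)

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        n_sims = 1000
        for seed in range(n_sims):
            e = np.random.default_rng(seed).normal(0, 1, 100)
            _, p = ljung_box(e, n_lags=24)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_df_validation(self):
        with pytest.raises(ValueError):
            ljung_box(np.random.default_rng(0).normal(size=50), n_lags=3, fitted_params=3)


class TestOutliers:
    def test_refit_with_no_events_equals_fit(self):
        series = ar1_monthly(120, seed=5)
        spec = ArimaSpec(1, 0, 0, 0, 0, 0, 12)
        a = tl.fit(series, spec)
        b = tl.refit_with_outliers(series, spec, [])
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_arimax_likelihood_dominates_nested_model(self):
        spec_gen = tl.GenSpec(
            arima_orders=(1, 0, 0, 0, 0, 0), ar=(0.6,), seed=11, outlier_events=((40, "AO", 8.0),)
        )
        series = tl.generate_monthly_volume(spec_gen, 150).series
        spec = ArimaSpec(1, 0, 0, 0, 0, 0, 12)
        base = tl.fit(series, spec)
        events = tl.detect_outliers(base)
        assert events, "an 8-sigma additive outlier must be detected"
        refit = tl.refit_with_outliers(series, spec, events, reference=base)
        assert refit.loglik >= base.loglik

    def test_rescan_after_integration_flags_nothing(self):
        spec_gen = tl.GenSpec(
            arima_orders=(1, 0, 0, 0, 0, 0), ar=(0.6,), seed=11, outlier_events=((40, "AO", 8.0),)
        )
        series = tl.generate_monthly_volume(spec_gen, 150).series
        base = tl.fit(series, ArimaSpec(1, 0, 0, 0, 0, 0, 12))
        events = tl.detect_outliers(base)
        integrated = tl.refit_with_outliers(series, base.spec, events, reference=base)
        assert tl.detect_outliers(integrated) == []

    def test_ao_magnitude_recovered(self):
        mags = []
        for seed in range(10):
            spec_gen = tl.GenSpec(
                arima_orders=(1, 0, 0, 0, 0, 0),
                ar=(0.6,),
                seed=seed,
                outlier_events=((30, "AO", 8.0),),
            )
            series = tl.generate_monthly_volume(spec_gen, 150).series
            events = tl.detect_outliers(tl.fit(series, ArimaSpec(1, 0, 0, 0, 0, 0, 12)))
            hit = [e for e in events if e.position == 30 and e.type == "AO"]
            if hit:
                mags.append(hit[0].magnitude)
        assert mags and abs(float(np.median(mags)) - 8.0) <= 0.3 * 8.0


class TestSelectModel:
    def test_grid_of_size_one_equals_fit(self):
        series = ar1_monthly(120, seed=2)
        spec = ArimaSpec(1, 0, 0, 0, 0, 0, 12)
        chosen = tl.select_model(series, [spec])
        direct = tl.fit(series, spec)
        assert chosen.spec == direct.spec
        assert chosen.aicc == pytest.approx(direct.aicc, abs=1e-9)

    def test_recovers_seasonal_structure(self):
        hits = 0
        for seed in range(5):
            spec = tl.GenSpec(
                arima_orders=(1, 0, 0, 0, 1, 1), ar=(0.5,), seasonal_ma=(-0.6,), seed=seed
            )
            series = tl.generate_monthly_volume(spec, 120).series
            model = tl.select_model(series, SMALL_GRID)
            hits += model.spec.D == 1 or model.spec.Q >= 1 or model.spec.P >= 1
        assert hits >= 4

    def test_prefers_parsimony_on_white_noise(self):
        hits = 0
        for seed in range(5):
            series = make_monthly(np.random.default_rng(seed).normal(50, 5, 120))
            model = tl.select_model(series, SMALL_GRID)
            hits += model.spec.n_arma_params <= 1
        assert hits >= 4

    def test_selection_is_deterministic(self):
        series = ar1_monthly(120, seed=9)
        a = tl.select_model(series, SMALL_GRID)
        b = tl.select_model(series, SMALL_GRID)
        assert a.spec == b.spec
        assert a.aicc == b.aicc
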