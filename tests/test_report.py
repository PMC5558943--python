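"""Idealized patterns, grid arithmetic, execution, and summaries."""

import dataclasses

import numpy as np
import pytest

import trendlag as tl
from trendlag.arima import ArimaSpec
from trendlag.report import (
    OVERDOSE_TERMS,
    SeriesStore,
    TermSpec,
    build_ideal,
    count_grid,
    reference_design,
    short_series,
)


class TestBuildIdeal:
    def test_pro_suicide_younger_pattern(self):
        ideal = build_ideal("pro_suicide", "younger")
        assert ideal.expected_r == {
            -3: pytest.approx(0.20),
            -2: pytest.approx(0.30),
            -1: pytest.approx(0.40),
            0: pytest.approx(0.50),
        }

    def test_prevention_total_is_negative_mirror(self):
        ideal = build_ideal("prevention", "total")
        assert ideal.expected_r == {
            -3: pytest.approx(-0.10),
            -2: pytest.approx(-0.20),
            -1: pytest.approx(-0.30),
            0: pytest.approx(-0.40),
        }
        assert ideal.expected_sign == -1

    def test_step_rule_holds_for_every_class_and_stratum(self):
        for term_class in ("pro_suicide", "prevention", "depression"):
            for stratum in ("total", "younger", "older", "older_men", "older_women", "men", "women"):
                ideal = build_ideal(term_class, stratum)
                for lag in (-3, -2, -1):
                    step = ideal.expected_r[lag + 1] - ideal.expected_r[lag]
                    assert step == pytest.approx(0.10 * ideal.expected_sign)

    def test_overdose_strata_swap_magnitudes(self):
        assert build_ideal("pro_suicide", "women").expected_r[0] == pytest.approx(0.50)
        assert build_ideal("pro_suicide", "men").expected_r[0] == pytest.approx(0.40)

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError):
            build_ideal("pro_suicide", "children")


class TestDesignArithmetic:
    def test_reference_grid_has_1043_coefficients(self):
        assert count_grid(reference_design()) == 1043

    def test_single_cell_design_counts_lags(self):
        design = tl.AnalysisDesign(terms=(TermSpec("t", "pro_suicide", "XX"),), strata=("total",))
        assert count_grid(design) == 7

    def test_empty_design_counts_zero(self):
        assert count_grid(tl.AnalysisDesign(terms=())) == 0

    def test_short_series_rule_on_reference_catalogue(self):
        short = short_series(50)
        assert len(short) == 8
        assert min(t.n_months for t in reference_design().terms) == 37

    def test_overdose_terms_get_extra_strata(self):
        design = reference_design()
        for label in OVERDOSE_TERMS:
            assert design.extra_strata[label] == ("men", "women")


class TestSummarize:
    def _cell_with(self, r_values, significant, term_class="pro_suicide", stratum="total"):
        lags = np.arange(-3, 4)
        result = tl.CcfResult(
            lags=lags,
            r=np.asarray(r_values, dtype=float),
            n_pairs=np.full(7, 60),
            band=np.full(7, 0.25),
            significant=np.asarray(significant),
        )
        return tl.GridCell(
            term=TermSpec("t", term_class, "XX"),
            stratum=stratum,
            result=result,
            ideal=build_ideal(term_class, stratum),
        )

    def test_bin_boundaries_lower_inclusive(self):
        cell = self._cell_with([0.55, -0.35, 0.15, 0.05, 0.50, 0.30, 0.10], [False] * 7)
        report = tl.summarize([cell])
        # .55/.50 large; -.35/.30 medium; .15/.10 small; .05 negligible
        assert report.bin_counts == (2, 2, 2, 1)
        assert report.n_coefficients == 7

    def test_perfect_pattern_match_scores_one(self):
        sig = [False, True, True, True, False, False, False]
        cell = self._cell_with([0.1, 0.3, 0.4, 0.5, 0.0, 0.0, 0.0], sig)
        report = tl.summarize([cell])
        assert report.concordance[("XX", "t", "total")] == pytest.approx(1.0)

    def test_wrong_sign_and_positive_lags_discordant(self):
        sig = [False, True, False, False, False, True, False]
        cell = self._cell_with([0.0, -0.4, 0.0, 0.0, 0.0, 0.3, 0.0], sig)
        report = tl.summarize([cell])
        assert report.concordance[("XX", "t", "total")] == pytest.approx(-1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tl.summarize([])


class TestRunGrid:
    SPEC = tl.GenSpec(arima_orders=(1, 0, 0, 0, 1, 1), ar=(0.5,), seasonal_ma=(-0.6,))

    @staticmethod
    def _selector(series):
        return tl.fit(series, ArimaSpec(1, 0, 0, 0, 1, 1, 12))

    def test_single_cell_grid(self):
        design = tl.AnalysisDesign(terms=(TermSpec("a", "pro_suicide", "XX"),), strata=("total",))
        store = tl.simulate_store(design, seed=1, n_months=84, gen_spec=self.SPEC)
        cells = tl.run_grid(store, design, model_selector=self._selector)
        assert len(cells) == 1
        assert cells[0].error is None
        assert len(cells[0].result.r) == 7

    def test_missing_series_reported_per_cell(self):
        design = tl.AnalysisDesign(terms=(TermSpec("a", "pro_suicide", "XX"),), strata=("total",))
        store = SeriesStore(volumes={}, outcomes={})
        cells = tl.run_grid(store, design, model_selector=self._selector)
        assert cells[0].error is not None and cells[0].result is None

    def test_injected_association_recovered_among_null_cells(self):
        terms = tuple(TermSpec(f"t{i}", "pro_suicide", "XX") for i in range(5))
        design = tl.AnalysisDesign(terms=terms, strata=("total", "older"))
        transfer = tl.TransferSpec(target_ccf=0.5, lag=-2)
        hits = 0
        for seed in range(5):
            store = tl.simulate_store(
                design,
                seed=seed,
                n_months=84,
                gen_spec=self.SPEC,
                injected={("XX", "total"): ("t0", transfer)},
            )
            cells = tl.run_grid(store, design, model_selector=self._selector)
            target = next(c for c in cells if c.term.label == "t0" and c.stratum == "total")
            hits += target.result.peak_lag() == -2
        assert hits >= 4

    def test_heatmap_export_roundtrip(self, tmp_path):
        design = tl.AnalysisDesign(
            terms=(TermSpec("a", "pro_suicide", "XX"),), strata=("total", "older")
        )
        store = tl.simulate_store(design, seed=3, n_months=84, gen_spec=self.SPEC)
        cells = tl.run_grid(store, design, model_selector=self._selector)
        path = tmp_path / "heatmap.csv"
        frame = tl.export_heatmap(cells, path)
        assert len(frame) == count_grid(design)
        back = tl.read_heatmap(path)
        np.testing.assert_allclose(back["r"].to_numpy(), frame["r"].to_numpy(), atol=1e-12)
        assert (back["significant"] == frame["significant"]).all()

    def test_end_to_end_determinism(self, tmp_path):
        design = tl.AnalysisDesign(terms=(TermSpec("a", "depression", "XX"),), strata=("total",))
        outputs = []
        for _ in range(2):
            store = tl.simulate_store(design, seed=5, n_months=84, gen_spec=self.SPEC)
            cells = tl.run_grid(store, design, model_selector=self._selector)
            report = tl.summarize(cells)
            path = tmp_path / f"summary{_}.json"
            report.to_json(path)
            outputs.append(path.read_text())
        assert outputs[0] == outputs[1]
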