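"""Calibration ratios, fold differences, acquisition-mode classification
and divergence-to-calendar-time conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codiverge.transmission import (
    RateCalibration,
    calibrate_time,
    classify_mode,
    compare_to_calibrations,
    ks_ratio,
    load_calibrations,
)


@pytest.fixture(scope="module")
def calibrations():
    return load_calibrations()


class TestKsRatio:
    @pytest.mark.parametrize(
        "symb, host, expected",
        [
            (3e-5, 1.2e-1, 0.00025),
            (3.7e-3, 1.22e-2, 0.30),
            (2.5e-3, 1.95e-2, 0.13),
            (1e-4, 6.8e-3, 0.015),
            (1.0, 1.0, 1.0),
        ],
    )
    def test_two_significant_figures(self, symb, host, expected):
        assert ks_ratio(symb, host) == pytest.approx(expected)

    def test_zero_host_rejected(self):
        with pytest.raises(ValueError):
            ks_ratio(1e-5, 0.0)

    def test_bundled_table_self_consistent(self, calibrations):
        """Every bundled row's printed ratio is reproduced from its own
        k_s values at two significant figures."""
        assert len(calibrations) == 8
        for entry in calibrations:
            assert entry.recomputed_ratio() == pytest.approx(entry.ratio)


class TestCompareToCalibrations:
    def test_fold_differences(self, calibrations):
        comp = compare_to_calibrations(
            0.00025, [e for e in calibrations if e.cladogenic]
        )
        folds = sorted(comp.folds.values())
        assert comp.min_fold == pytest.approx(60, rel=1e-6)
        assert comp.max_fold == pytest.approx(1200, rel=1e-6)
        assert len(folds) == 7

    def test_observed_equal_to_calibration_is_one_fold(self, calibrations):
        nasonia = next(e for e in calibrations if "Nasonia" in e.host_a)
        comp = compare_to_calibrations(nasonia.ratio, [nasonia])
        assert comp.min_fold == pytest.approx(1.0)

    def test_nonpositive_observed_rejected(self, calibrations):
        with pytest.raises(ValueError):
            compare_to_calibrations(0.0, calibrations)


class TestClassifyMode:
    def test_observed_divergences_without_mito(self, calibrations):
        call = classify_mode(1.2e-1, 3e-5, calibrations)
        assert call.mode == "noncladogenic_transfer"
        assert min(call.fold_differences.values()) >= 60

    def test_ratio_at_calibration_median_is_cladogenic(self, calibrations):
        ratios = sorted(e.ratio for e in calibrations if e.cladogenic)
        med = ratios[len(ratios) // 2]
        call = classify_mode(1.0, med, calibrations)
        assert call.mode == "cladogenic_plausible"

    def test_nasonia_like_ratio_is_cladogenic(self, calibrations):
        call = classify_mode(1.22e-2, 3.7e-3, calibrations)
        assert call.mode == "cladogenic_plausible"

    def test_introgression_pattern_with_mito(self, calibrations):
        # mito and rescaled symbiont agree at a tenth of the nuclear age
        call = classify_mode(
            1.0, 0.13 * 0.1, calibrations, mito_div=0.1
        )
        assert call.mode == "introgression"

    def test_horizontal_pattern_with_mito(self, calibrations):
        # mito concordant with nuclear, symbiont far younger
        call = classify_mode(1.0, 0.13 * 0.01, calibrations, mito_div=1.0)
        assert call.mode == "horizontal"

    def test_cladogenic_pattern_with_mito(self, calibrations):
        call = classify_mode(1.0, 0.13, calibrations, mito_div=1.0)
        assert call.mode == "cladogenic_plausible"

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        cal = load_calibrations()
        base = classify_mode(1.2e-1, 3e-5, cal, mito_div=1.1e-1)
        scaled = classify_mode(
            1.2e-1 * scale, 3e-5 * scale, cal, mito_div=1.1e-1 * scale
        )
        assert base.mode == scaled.mode

    def test_nonpositive_divergence_rejected(self, calibrations):
        with pytest.raises(ValueError):
            classify_mode(0.0, 1e-5, calibrations)


class TestCalibrateTime:
    def test_pairwise_convention_year_rate(self):
        """Symbiont k_s over a per-year pairwise rate: ~6,400 years."""
        cal = RateCalibration(
            rate=4.7e-9,
            interval=(4.7e-9, 4.7e-9),
            units="per-site-per-year",
            convention="pairwise_divergence",
        )
        t = calibrate_time(3e-5, cal)
        assert t.rounded() == 6400

    def test_per_lineage_convention_generation_rate(self):
        """Third-position divergence over a per-generation lineage rate at
        10 generations/year: ~1,600 years at the fast end."""
        cal = RateCalibration(
            rate=1.29e-9,
            interval=(2.88e-10, 1.29e-9),
            units="per-site-per-generation",
            convention="per_lineage",
            generations_per_year=10,
        )
        t = calibrate_time(4.0e-5, cal)
        assert t.rounded() == 1600
        lo, hi = t.rounded_interval()
        assert lo == 1600  # fast rate end
        assert hi == pytest.approx(6900)

    def test_linearity_in_divergence(self):
        cal = RateCalibration(
            rate=1e-9,
            interval=(5e-10, 2e-9),
            units="per-site-per-year",
            convention="pairwise_divergence",
        )
        t1 = calibrate_time(1e-5, cal)
        t2 = calibrate_time(2e-5, cal)
        assert t2.years == pytest.approx(2 * t1.years)

    def test_faster_rate_gives_younger_age(self):
        slow = RateCalibration(
            rate=1e-9, interval=(1e-9, 1e-9),
            units="per-site-per-year", convention="pairwise_divergence",
        )
        fast = RateCalibration(
            rate=4e-9, interval=(4e-9, 4e-9),
            units="per-site-per-year", convention="pairwise_divergence",
        )
        assert calibrate_time(1e-5, fast).years < calibrate_time(1e-5, slow).years

    def test_generation_rate_without_generations_rejected(self):
        with pytest.raises(ValueError):
            RateCalibration(
                rate=1e-9,
                interval=(1e-9, 1e-9),
                units="per-site-per-generation",
                convention="per_lineage",
            )


class TestScenarioClassification:
    """End-to-end: simulate an acquisition scenario, estimate divergences
    with the pipeline, classify, and recover the planted mode."""

    @pytest.mark.parametrize("mode", ["introgression", "horizontal"])
    def test_mode_recovery_with_mito(self, mode):
        from codiverge.kaks import ka_ks_pair
        from codiverge.ortholog_io import concatenate
        from codiverge.synthetic_data import ScenarioConfig, simulate_scenario

        cfg = ScenarioConfig(mode=mode, seed=42, symbiont_bp=120_000, symbiont_genes=120)
        res = simulate_scenario(cfg)
        cal = load_calibrations()
        nuc = concatenate(res.nuclear)
        mito = concatenate(res.mito)
        symb = concatenate(res.symbiont)
        ha, hb, _ = cfg.host_taxa
        sa, sb, _ = cfg.symbiont_taxa
        nuclear_ks = ka_ks_pair(nuc, ha, hb).ks
        mito_ks = ka_ks_pair(mito, ha, hb).ks
        symb_ks = ka_ks_pair(symb, sa, sb).ks
        call = classify_mode(nuclear_ks, symb_ks, cal, mito_div=mito_ks)
        assert call.mode == mode

    def test_cladogenic_preset_at_nasonia_ratio(self):
        from codiverge.kaks import ka_ks_pair
        from codiverge.ortholog_io import concatenate
        from codiverge.synthetic_data import ScenarioConfig, simulate_scenario

        cfg = ScenarioConfig(
            mode="cladogenic", seed=43, calibration_ratio=0.30,
            symbiont_bp=120_000, symbiont_genes=120,
        )
        res = simulate_scenario(cfg)
        cal = load_calibrations()
        ha, hb, _ = cfg.host_taxa
        sa, sb, _ = cfg.symbiont_taxa
        nuclear_ks = ka_ks_pair(concatenate(res.nuclear), ha, hb).ks
        symb_ks = ka_ks_pair(concatenate(res.symbiont), sa, sb).ks
        call = classify_mode(nuclear_ks, symb_ks, cal)
        assert call.mode == "cladogenic_plausible"
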