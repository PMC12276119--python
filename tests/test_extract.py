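"""Window-maximum peak extraction, noise amplitude and blank statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imsquant import (
    AggregationMode,
    IMSChromatogram,
    MSTrace,
    PeakWindow,
    Species,
    aggregate_species,
    blank_statistics,
    noise_gamma,
    peak_height,
    sn_ratio,
)
from imsquant.extract import PeakMeasurement


def flat_chrom(value=0.5, nr=41, nd=61):
    rt = 2.0 * np.arange(nr)
    dt = 0.9 + 0.005 * np.arange(nd)
    return IMSChromatogram(rt, dt, np.full((nr, nd), float(value)))


WINDOW = PeakWindow("x", Species.MONOMER, (10.0, 70.0), (0.95, 1.15))


class TestPeakHeight:
    def test_constant_matrix_has_zero_height(self):
        assert peak_height(flat_chrom(0.7), WINDOW).height == 0.0

    def test_single_spike_height_is_amplitude(self):
        chrom = flat_chrom(0.2)
        chrom.intensity[20, 30] += 1.5
        m = peak_height(chrom, WINDOW)
        assert m.height == pytest.approx(1.5)
        assert m.rt_at_max == pytest.approx(chrom.retention_axis[20])
        assert m.dt_at_max == pytest.approx(chrom.drift_axis[30])
        assert m.baseline_used == pytest.approx(0.2)

    def test_tie_breaks_to_smallest_retention_then_drift(self):
        chrom = flat_chrom(0.0)
        for idx in [(25, 35), (15, 40), (15, 25)]:
            chrom.intensity[idx] = 2.0
        m = peak_height(chrom, WINDOW)
        assert m.rt_at_max == pytest.approx(chrom.retention_axis[15])
        assert m.dt_at_max == pytest.approx(chrom.drift_axis[25])

    def test_window_outside_axes_rejected(self):
        with pytest.raises(ValueError):
            peak_height(flat_chrom(), PeakWindow("x", Species.MONOMER, (10, 500), (0.95, 1.15)))
        with pytest.raises(ValueError):
            peak_height(flat_chrom(), PeakWindow("x", Species.MONOMER, (10, 70), (0.5, 1.15)))

    def test_ms_trace_height_against_edge_baseline(self):
        rt = 0.01 * np.arange(1000)
        y = np.full(1000, 3.0)
        y[500] = 8.0
        m = peak_height(MSTrace(rt, y), PeakWindow("x", Species.MONOMER, (2.0, 8.0)))
        assert m.height == pytest.approx(5.0)
        assert m.dt_at_max is None

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(offset=st.floats(0, 10))
    def test_translation_equivariance(self, offset):
        chrom = flat_chrom(0.1)
        rng = np.random.default_rng(0)
        chrom.intensity += rng.random(chrom.intensity.shape)
        base = peak_height(chrom, WINDOW).height
        shifted = IMSChromatogram(
            chrom.retention_axis, chrom.drift_axis, chrom.intensity + offset
        )
        assert peak_height(shifted, WINDOW).height == pytest.approx(base)

    def test_monotone_in_signal(self):
        chrom = flat_chrom(0.1)
        rng = np.random.default_rng(1)
        chrom.intensity += rng.random(chrom.intensity.shape)
        base = peak_height(chrom, WINDOW).height
        boosted = IMSChromatogram(
            chrom.retention_axis, chrom.drift_axis, chrom.intensity.copy()
        )
        # raise interior in-window cells only; border (baseline) untouched
        boosted.intensity[6:34, 11:50] += 0.5
        assert peak_height(boosted, WINDOW).height >= base


class TestNoiseGamma:
    def test_noiseless_flat_blank_gives_zero(self):
        assert noise_gamma(flat_chrom(0.3), WINDOW).gamma == 0.0

    def test_gamma_bounds_for_gaussian_noise(self):
        # max of ~1000 in-window cells sits a few sd above the baseline
        sd = 0.05
        gammas = []
        for seed in range(10):
            chrom = flat_chrom(0.2)
            rng = np.random.default_rng(seed)
            chrom.intensity += rng.normal(0, sd, chrom.intensity.shape)
            chrom.intensity = np.clip(chrom.intensity, 0, None)
            gammas.append(noise_gamma(chrom, WINDOW).gamma)
        assert all(2 * sd < g < 6 * sd for g in gammas)

    def test_gamma_scales_linearly_with_noise_sd(self):
        def gamma_at(sd):
            chrom = flat_chrom(5.0)
            rng = np.random.default_rng(3)
            chrom.intensity += rng.normal(0, sd, chrom.intensity.shape)
            return noise_gamma(chrom, WINDOW).gamma

        assert gamma_at(0.2) == pytest.approx(2 * gamma_at(0.1), rel=1e-9)

    def test_contaminant_peak_dominates_gamma(self):
        chrom = flat_chrom(0.1)
        chrom.intensity[20, 30] += 0.8
        assert noise_gamma(chrom, WINDOW).gamma >= 0.8


class TestSNRatio:
    @pytest.mark.parametrize(
        "h,g,expected", [(1.5, 1.0, 3.0), (0.0, 1.0, 0.0), (2.4, 0.048, 100.0)]
    )
    def test_values(self, h, g, expected):
        assert sn_ratio(h, g) == pytest.approx(expected)

    def test_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            sn_ratio(1.0, 0.0)


def measurement(species, height):
    w = PeakWindow("nonanal", species, (0.0, 10.0), (1.1, 1.3))
    return PeakMeasurement(w, height, 5.0, 1.2, 0.1)


class TestAggregateSpecies:
    def test_sum_mode_adds_monomer_and_dimer(self):
        ms = [measurement(Species.MONOMER, 0.2), measurement(Species.DIMER, 0.15)]
        assert aggregate_species(ms, AggregationMode.MONOMER_PLUS_DIMER) == pytest.approx(0.35)

    def test_monomer_only_ignores_dimer(self):
        ms = [measurement(Species.MONOMER, 0.2), measurement(Species.DIMER, 0.15)]
        assert aggregate_species(ms, "monomer_only") == pytest.approx(0.2)

    def test_absent_dimer_counts_as_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = aggregate_species(
                [measurement(Species.MONOMER, 0.2)], AggregationMode.MONOMER_PLUS_DIMER
            )
        assert out == pytest.approx(0.2)
        assert "dimer" in caplog.text

    def test_missing_monomer_rejected(self):
        with pytest.raises(ValueError):
            aggregate_species([measurement(Species.DIMER, 0.1)], "monomer_only")


class TestBlankStatistics:
    def test_hand_computed_mean_and_sd(self):
        # heights 0.27/0.35/0.43 via single-spike blanks
        blanks = []
        for h in (0.27, 0.35, 0.43):
            chrom = flat_chrom(0.0)
            chrom.intensity[20, 30] = h
            blanks.append(chrom)
        stats_ = blank_statistics(blanks, [WINDOW], "monomer_only")
        assert stats_.mean == pytest.approx(0.35)
        assert stats_.sd == pytest.approx(0.08)

    def test_identical_blanks_zero_sd(self):
        blanks = [flat_chrom(0.2) for _ in range(4)]
        for b in blanks:
            b.intensity[20, 30] = 1.0
        stats_ = blank_statistics(blanks, [WINDOW], "monomer_only")
        assert stats_.sd == 0.0

    def test_single_blank_rejected(self):
        with pytest.raises(ValueError):
            blank_statistics([flat_chrom()], [WINDOW], "monomer_only")
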