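"""Mass-action response model and chromatogram/trace generators."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imsquant import (
    CompoundSpec,
    ResponseModel,
    default_contaminants,
    generate_blank,
    generate_calibration_series,
    generate_ms_trace,
    ionization_response,
    render_chromatogram,
)
from imsquant.extract import PeakWindow, Species, peak_height

from conftest import make_compound


class TestIonizationResponse:
    def test_no_analyte_leaves_full_reservoir(self):
        model = ResponseModel(r0=6.0)
        assert ionization_response(0.0, model) == (0.0, 0.0, 6.0)

    @pytest.mark.parametrize(
        "alpha,beta,c,expected",
        [
            (1.0, 1.0, 1.0, (1 / 3, 1 / 3, 1 / 3)),  # q = 3
            (1.0, 0.0, 1.0, (0.5, 0.0, 0.5)),  # q = 2, no dimer channel
        ],
    )
    def test_closed_form(self, alpha, beta, c, expected):
        model = ResponseModel(r0=1.0, alpha=alpha, beta=beta, ceiling=2.0)
        out = ionization_response(c, model)
        assert out == pytest.approx(expected)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            ionization_response(-0.1, ResponseModel())

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        c=st.floats(0, 1e4),
        alpha=st.floats(1e-3, 10),
        beta=st.floats(0, 10),
        r0=st.floats(0.1, 100),
    )
    def test_charge_conservation(self, c, alpha, beta, r0):
        model = ResponseModel(r0=r0, alpha=alpha, beta=beta, ceiling=2 * r0)
        m, d, r = ionization_response(c, model)
        assert m + d + r == pytest.approx(r0, abs=1e-12 * r0)
        assert m >= 0 and d >= 0 and r >= 0

    def test_monomer_peaks_at_inverse_sqrt_alpha_beta(self):
        model = ResponseModel(r0=6.0, alpha=2.0, beta=0.5, ceiling=12.0)
        c_star = 1 / np.sqrt(model.alpha * model.beta)
        grid = np.linspace(0.01, 10 * c_star, 5001)
        monomer = np.array([ionization_response(c, model).monomer for c in grid])
        assert grid[np.argmax(monomer)] == pytest.approx(c_star, rel=0.01)
        # interior maximum: rises before, falls after
        m_star = ionization_response(c_star, model).monomer
        assert m_star > monomer[0] and m_star > monomer[-1]

    def test_summed_signal_saturates_monotonically(self):
        model = ResponseModel(r0=6.0, alpha=1.0, beta=0.05, ceiling=12.0)
        grid = np.geomspace(0.01, 1e4, 200)
        total = np.array(
            [sum(ionization_response(c, model)[:2]) for c in grid]
        )
        assert np.all(np.diff(total) > 0)
        assert total[-1] == pytest.approx(model.r0, rel=1e-3)


class TestRenderChromatogram:
    def test_empty_noise_free_is_baseline_plus_rip(self, small_axes):
        det = ResponseModel(noise_sd=0.0)
        chrom = render_chromatogram([], [], axes=small_axes, seed=0, detector=det)
        j_rip = np.argmin(np.abs(chrom.drift_axis - 1.0))
        assert chrom.intensity[:, j_rip] == pytest.approx(det.r0 + det.baseline)
        far = chrom.intensity[:, chrom.drift_axis > 1.2]
        assert far == pytest.approx(det.baseline)

    def test_peak_height_matches_response_model(self, small_axes, hexanone_noise_free):
        comp = hexanone_noise_free
        amount = 0.5
        chrom = render_chromatogram([comp], [amount], axes=small_axes, seed=0)
        expected = ionization_response(amount, comp.model).monomer
        window = PeakWindow(
            comp.name,
            Species.MONOMER,
            (comp.rt_monomer - 20, comp.rt_monomer + 20),
            (comp.dt_monomer - 0.05, comp.dt_monomer + 0.05),
        )
        height = peak_height(chrom, window).height
        assert height == pytest.approx(expected, rel=0.02)

    def test_identical_seeds_identical_output(self, small_axes, hexanone):
        a = render_chromatogram([hexanone], [1.0], axes=small_axes, seed=42)
        b = render_chromatogram([hexanone], [1.0], axes=small_axes, seed=42)
        assert np.array_equal(a.intensity, b.intensity)

    def test_position_outside_axes_rejected(self, small_axes):
        comp = make_compound(rt=2000.0)
        with pytest.raises(ValueError, match="outside axes"):
            render_chromatogram([comp], [1.0], axes=small_axes, seed=0)

    def test_intensities_clipped_to_ceiling(self, small_axes, hexanone):
        chrom = render_chromatogram([hexanone], [100.0], axes=small_axes, seed=0)
        assert chrom.intensity.max() <= hexanone.model.ceiling
        assert chrom.intensity.min() >= 0


class TestGenerateBlank:
    def test_fewer_than_two_blanks_rejected(self):
        with pytest.raises(ValueError):
            generate_blank(default_contaminants(), n=1, seed=0)

    def test_no_contaminants_no_noise_is_flat(self, small_axes):
        det = ResponseModel(noise_sd=0.0)
        blanks = generate_blank([], n=2, seed=0, axes=small_axes, detector=det)
        for b in blanks:
            off_rip = b.intensity[:, b.drift_axis > 1.2]
            assert off_rip == pytest.approx(det.baseline)

    def test_contaminant_heights_reproduce_configured_levels(self):
        # nonanal-like contaminant: blank window heights should scatter
        # around the configured mean within Monte-Carlo error
        from imsquant.synthetic import AxisSpec

        contaminants = [c for c in default_contaminants() if c[0].name == "nonanal"]
        comp, mean_ng, _ = contaminants[0]
        axes = AxisSpec(rt_start=1500.0, rt_stop=1660.0, rt_step=2.0)
        n = 12
        blanks = generate_blank(contaminants, n=n, seed=7, axes=axes)
        mono_w = PeakWindow(
            comp.name,
            Species.MONOMER,
            (comp.rt_monomer - 24, comp.rt_monomer + 24),
            (comp.dt_monomer - 0.05, comp.dt_monomer + 0.05),
        )
        dim_w = PeakWindow(
            comp.name,
            Species.DIMER,
            (comp.rt_monomer - 24, comp.rt_monomer + 24),
            (comp.dt_dimer - 0.05, comp.dt_dimer + 0.05),
        )
        sums = [
            peak_height(b, mono_w).height + peak_height(b, dim_w).height
            for b in blanks
        ]
        m, d, _ = ionization_response(mean_ng, comp.model)
        observed = np.mean(sums)
        se = np.std(sums, ddof=1) / np.sqrt(n)
        # window-max reading carries a small positive noise bias, hence 3 SE
        # around the model expectation plus up to ~4 noise sd
        assert m + d - 3 * se < observed < m + d + 4 * comp.model.noise_sd + 3 * se


class TestCalibrationSeries:
    def test_level_zero_gives_blanks(self, small_axes, hexanone_noise_free):
        series = generate_calibration_series(
            hexanone_noise_free, [0.0], replicates=3, seed=0, axes=small_axes
        )
        assert len(series) == 3
        det = hexanone_noise_free.model
        for chrom in series:
            off_rip = chrom.intensity[:, chrom.drift_axis > 1.2]
            assert off_rip == pytest.approx(det.baseline)

    def test_monomer_nonmonotonic_sum_monotonic(self, small_axes):
        model_kwargs = dict(alpha=1.0, beta=1.0, noise_sd=0.0)
        comp = make_compound(**model_kwargs)  # c* = 1 ng/tube, inside the span
        levels = [round(float(v), 4) for v in np.geomspace(0.01, 100, 18)]
        series = generate_calibration_series(
            comp, levels, replicates=1, seed=0, axes=small_axes
        )
        mono_w = PeakWindow(
            comp.name, Species.MONOMER, (960, 1000), (1.14, 1.24)
        )
        dim_w = PeakWindow(comp.name, Species.DIMER, (960, 1000), (1.42, 1.52))
        mono = [peak_height(c, mono_w).height for c in series]
        total = [
            peak_height(c, mono_w).height + peak_height(c, dim_w).height
            for c in series
        ]
        assert np.argmax(mono) not in (0, len(mono) - 1)  # interior maximum
        assert np.all(np.diff(total) > -1e-9)

    def test_unsorted_levels_rejected(self, hexanone):
        with pytest.raises(ValueError):
            generate_calibration_series(hexanone, [1.0, 0.1], 3, seed=0)

    def test_determinism(self, small_axes, hexanone):
        a = generate_calibration_series(hexanone, [0.1, 1.0], 2, seed=5, axes=small_axes)
        b = generate_calibration_series(hexanone, [0.1, 1.0], 2, seed=5, axes=small_axes)
        for x, y in zip(a, b):
            assert np.array_equal(x.intensity, y.intensity)


class TestMSTrace:
    def test_blank_trace_is_baseline_only(self):
        t = generate_ms_trace([10.0], [0.0], ms_noise_sd=0.0, baseline=2.0)
        assert t.intensity == pytest.approx(2.0)

    def test_noise_free_response_is_linear_through_origin(self):
        amounts = [1.0, 10.0, 100.0, 1000.0]
        heights = []
        for a in amounts:
            t = generate_ms_trace([10.0], [a], ms_gain=2.0, ms_noise_sd=0.0)
            heights.append(t.intensity.max() - 1.0)  # subtract baseline
        res = stats.linregress(amounts, heights)
        assert res.rvalue**2 > 0.999
        assert res.slope == pytest.approx(2.0, rel=1e-6)

    def test_determinism_and_negative_gain(self):
        a = generate_ms_trace([5.0], [3.0], seed=9)
        b = generate_ms_trace([5.0], [3.0], seed=9)
        assert np.array_equal(a.intensity, b.intensity)
        with pytest.raises(ValueError):
            generate_ms_trace([5.0], [3.0], ms_gain=-1.0)


class TestInvariantsOfSpecs:
    def test_compound_requires_dimer_slower_than_monomer(self):
        with pytest.raises(ValueError):
            CompoundSpec("bad", 100.0, 1.5, 1.2)
        with pytest.raises(ValueError):
            CompoundSpec("bad", 100.0, 0.95, 1.2)

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            ResponseModel(r0=-1.0)
        with pytest.raises(ValueError):
            ResponseModel(r0=6.0, ceiling=3.0)
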