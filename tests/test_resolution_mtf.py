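"""Circular-edge MTF pipeline against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.special import erf

from phantomiq.core import ProtocolDose
from phantomiq.resolution_mtf import (
    BinnedEsf,
    bar_pattern_modulation,
    bin_esf,
    esf_to_mtf,
    extract_circular_esf,
)
from phantomiq.synthetic_phantom import (
    PhantomSpec,
    apply_quantum_noise,
    apply_system_blur,
    gaussian_f_at,
    gaussian_mtf,
    render_resolution_module,
)


class TestExtractCircularEsf:
    def test_ideal_step_edge_plateaus(self, fine_mtf_spec):
        vol = render_resolution_module(fine_mtf_spec)
        samples = extract_circular_esf(
            vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
        inside = samples[samples[:, 0] < -0.3, 1]
        outside = samples[samples[:, 0] > 0.3, 1]
        assert np.allclose(inside, fine_mtf_spec.mtf_insert_hu)
        assert np.allclose(outside, fine_mtf_spec.background_hu)

    def test_blurred_edge_fits_gaussian_cdf(self, mtf_slice_factory, fine_mtf_spec):
        vol = mtf_slice_factory(0.5)
        samples = extract_circular_esf(
            vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
        b = bin_esf(samples, 0.01)

        def model(x, s, x0, lo, hi):
            return lo + (hi - lo) * 0.5 * (1 - erf((x - x0) / (s * math.sqrt(2))))

        p, _ = curve_fit(model, b.positions, b.values, p0=[0.5, 0, 100, 990])
        assert p[0] == pytest.approx(0.5, abs=0.02)

    def test_center_misset_recovers_edge_radius(self, mtf_slice_factory,
                                                fine_mtf_spec):
        # offset the provided center by 2 px; the refit must still place
        # the edge (ESF half-crossing) at the true radius within 0.1 mm
        vol = mtf_slice_factory(0.5)
        off_center = (fine_mtf_spec.center_rc[0] + 2.0,
                      fine_mtf_spec.center_rc[1] - 2.0)
        samples = extract_circular_esf(
            vol.voxels[0], off_center, 12.0, 8.0, 0.1)
        b = bin_esf(samples, 0.02)
        half = 0.5 * (b.values[:20].mean() + b.values[-20:].mean())
        crossing = np.interp(-half, -b.values, b.positions)  # descending
        assert abs(crossing) < 0.1

    def test_annulus_outside_image_rejected(self, fine_mtf_spec):
        vol = render_resolution_module(fine_mtf_spec)
        with pytest.raises(ValueError):
            extract_circular_esf(vol.voxels[0], (10.0, 10.0), 12.0, 8.0, 0.1)


class TestBinEsf:
    def test_constant_samples(self):
        samples = np.column_stack([np.linspace(-1, 1, 100), np.full(100, 7.0)])
        b = bin_esf(samples, 0.1)
        assert np.allclose(b.values, 7.0)

    def test_empty_interior_bins_interpolated(self):
        samples = np.array([[-1.0, 0.0], [-0.9, 0.0], [1.0, 10.0], [1.1, 10.0]])
        b = bin_esf(samples, 0.1)
        assert (b.counts == 0).any()
        assert np.all(np.diff(b.values) >= 0)   # monotone fill

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            bin_esf(np.empty((0, 2)), 0.1)

    def test_bin_width_convergence(self, mtf_slice_factory, fine_mtf_spec):
        vol = mtf_slice_factory(0.5)
        samples = extract_circular_esf(
            vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
        coarse = bin_esf(samples, 0.04)
        fine = bin_esf(samples, 0.02)
        interp = np.interp(coarse.positions, fine.positions, fine.values)
        # max deviation stays at the per-bin noise scale, i.e. well
        # under 0.5% of the 890 HU edge contrast
        assert np.max(np.abs(interp - coarse.values)) < 4.0


class TestEsfToMtf:
    @pytest.mark.parametrize("sigma", [0.3, 0.5, 0.8, 1.0])
    def test_gaussian_blur_oracle(self, sigma, mtf_slice_factory, fine_mtf_spec):
        vol = mtf_slice_factory(sigma, seed=5)
        samples = extract_circular_esf(
            vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
        curve = esf_to_mtf(bin_esf(samples, 0.01), 0.1)
        assert curve.values[0] == pytest.approx(1.0)
        assert curve.f50 == pytest.approx(gaussian_f_at(0.5, sigma), rel=0.03)
        assert curve.f10 == pytest.approx(gaussian_f_at(0.1, sigma), rel=0.03)
        assert curve.f50 < curve.f10

    def test_pixel_aperture_tracks_sinc(self):
        # no blur beyond pixel integration at 1.0 mm pixels: the MTF is
        # the aperture transform |sinc(f)| within 5% up to 0.4 lp/mm
        spec = PhantomSpec(matrix_size=64, pixel_spacing=1.0,
                           phantom_radius_mm=25.0, bar_groups=[], inserts=[],
                           n_slices=1, mtf_insert_diameter_mm=24.0)
        vol = render_resolution_module(spec)
        samples = extract_circular_esf(vol.voxels[0], spec.center_rc, 12.0, 6.0, 1.0)
        curve = esf_to_mtf(bin_esf(samples, 0.1), 1.0)
        for f in (0.1, 0.2, 0.3, 0.4):
            assert curve.at(f) == pytest.approx(abs(np.sinc(f)), abs=0.05)

    def test_hu_scaling_invariance(self, mtf_slice_factory, fine_mtf_spec):
        vol = mtf_slice_factory(0.5)
        samples = extract_circular_esf(
            vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
        doubled = samples.copy()
        doubled[:, 1] *= 2.0
        c1 = esf_to_mtf(bin_esf(samples, 0.01), 0.1)
        c2 = esf_to_mtf(bin_esf(doubled, 0.01), 0.1)
        assert np.allclose(c1.values, c2.values, atol=1e-9)

    def test_noise_robustness_of_f50(self, mtf_slice_factory, fine_mtf_spec):
        clean = mtf_slice_factory(0.5)
        noisy = mtf_slice_factory(0.5, seed=8)   # sigma 10 HU
        f50s = []
        for vol in (clean, noisy):
            samples = extract_circular_esf(
                vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
            f50s.append(esf_to_mtf(bin_esf(samples, 0.01), 0.1).f50)
        assert abs(f50s[1] - f50s[0]) / f50s[0] < 0.05

    def test_lp_cm_units(self, mtf_slice_factory, fine_mtf_spec):
        vol = mtf_slice_factory(0.5)
        samples = extract_circular_esf(
            vol.voxels[0], fine_mtf_spec.center_rc, 12.0, 8.0, 0.1)
        curve = esf_to_mtf(bin_esf(samples, 0.01), 0.1)
        assert curve.f50_lp_cm == pytest.approx(10 * curve.f50)


@pytest.fixture(scope="module")
def bar_spec():
    return PhantomSpec(pixel_spacing=0.2, matrix_size=512)


class TestBarPattern:
    def test_zero_contrast_modulation(self, bar_spec):
        spec = PhantomSpec(pixel_spacing=0.2, matrix_size=512,
                           bar_groups=[(0.6, 0.0, 6)])
        vol = render_resolution_module(spec)
        g = spec.bar_group_layout()[0]
        assert bar_pattern_modulation(vol.voxels[0], g, spec.background_hu) == 0.0

    def test_unblurred_modulation_near_unity(self, bar_spec):
        vol = render_resolution_module(bar_spec)
        g = bar_spec.bar_group_layout()[0]   # 0.2 lp/mm, wide bars
        m = bar_pattern_modulation(vol.voxels[0], g, bar_spec.background_hu)
        assert m == pytest.approx(1.0, abs=0.02)

    def test_blurred_modulation_tracks_mtf(self, bar_spec):
        # square-wave modulation at 0.6 lp/mm under 0.5 mm blur agrees
        # with the sine-wave MTF within the Coltman-consistent 0.05
        vol = apply_system_blur(render_resolution_module(bar_spec), 0.5)
        g = [x for x in bar_spec.bar_group_layout()
             if x["frequency_lp_mm"] == 0.6][0]
        m = bar_pattern_modulation(vol.voxels[0], g, bar_spec.background_hu)
        assert m == pytest.approx(float(gaussian_mtf(0.6, 0.5)), abs=0.05)
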