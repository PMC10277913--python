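"""Ground-truth properties of the digital phantom generator."""

import math

import numpy as np
import pytest

from phantomiq.core import ProtocolDose, RoiSpec
from phantomiq.synthetic_phantom import (
    AIR_HU,
    ConfigurationError,
    LayoutError,
    PhantomSpec,
    apply_quantum_noise,
    apply_system_blur,
    gaussian_f_at,
    render_hu_module,
    render_low_contrast_module,
    render_resolution_module,
    render_uniformity_module,
    simulate_catphan,
)
from phantomiq.uniformity_noise import roi_stats


class TestSpecValidation:
    def test_insert_outside_body_rejected(self):
        with pytest.raises(LayoutError):
            PhantomSpec(inserts=[(0.0, 44.0, 10.0, 990.0)])  # 44 + 5 > 45

    def test_unrepresentable_bar_frequency_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(pixel_spacing=1.0, bar_groups=[(0.6, 500.0, 4)])

    def test_grid_must_cover_phantom(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(matrix_size=64, pixel_spacing=1.0, phantom_radius_mm=45.0)


class TestHuModule:
    def test_insert_interior_hu_exact(self, default_spec, hu_volume):
        # noiseless rendering: voxels well inside the Teflon-like insert
        # take exactly the configured HU
        (r, c) = default_spec.insert_centers_rc()[0]
        block = hu_volume.voxels[0,
                                 int(r) - 3:int(r) + 4, int(c) - 3:int(c) + 4]
        assert np.allclose(block, 990.0)

    def test_hole_centers_spacing_in_pixels(self):
        spec = PhantomSpec(matrix_size=128, pixel_spacing=1.0,
                           bar_groups=[], rod_spacing_mm=50.0)
        (tl, tr, bl, br) = spec.hole_centers_rc()
        assert tr[1] - tl[1] == pytest.approx(50.0)  # px at 1 mm spacing
        assert bl[0] - tl[0] == pytest.approx(50.0)
        vol = render_hu_module(spec)
        # rendered holes are air at their centers
        for (r, c) in (tl, tr, bl, br):
            assert vol.voxels[0, int(r), int(c)] == pytest.approx(AIR_HU)

    def test_wire_centroid_shift_per_slice(self, default_spec, hu_volume):
        # in-plane displacement per slice = slice_spacing / tan(angle)
        spec = default_spec
        row = int(spec.center_rc[0] + spec.wire_row_offset_mm / spec.pixel_spacing)
        centroids = []
        for k in range(2, 6):
            band = hu_volume.voxels[k, row - 4:row + 5]
            prof = np.clip(band.mean(axis=0) - np.median(band.mean(axis=0)), 0, None)
            centroids.append(
                (prof * np.arange(prof.size)).sum() / prof.sum() * spec.pixel_spacing)
        expected = spec.slice_thickness / math.tan(math.radians(spec.wire_angle_deg))
        assert np.allclose(np.diff(centroids), expected, atol=0.02)
        assert expected == pytest.approx(2.943, abs=2e-3)


class TestResolutionAndLowContrast:
    def test_bar_period_definition(self):
        spec = PhantomSpec(pixel_spacing=0.2, matrix_size=512,
                           bar_groups=[(0.6, 500.0, 4)])
        g = spec.bar_group_layout()[0]
        assert g["width_px"] * 0.2 / g["pairs"] == pytest.approx(1.0 / 0.6)

    def test_zero_contrast_bars_invisible(self):
        spec = PhantomSpec(pixel_spacing=0.5, bar_groups=[(0.6, 0.0, 4)],
                           inserts=[], mtf_insert_hu=100.0, n_slices=1)
        vol = render_resolution_module(spec)
        uniform = render_uniformity_module(spec)
        assert np.array_equal(vol.voxels, uniform.voxels)

    def test_low_contrast_disk_hu(self):
        # 1% contrast on a 100-HU background: disk is exactly 1 HU above
        spec = PhantomSpec(background_hu=100.0, n_slices=1,
                           low_contrast_disks=[(15.0, 1.0)])
        vol = render_low_contrast_module(spec)
        g = spec.low_contrast_layout()[0]
        r, c = (int(round(x)) for x in g["center_rc"])
        assert vol.voxels[0, r, c] == pytest.approx(101.0)

    def test_disk_layout_echo(self):
        spec = PhantomSpec()
        diameters = [g["diameter_mm"] for g in spec.low_contrast_layout()]
        assert diameters == [15.0, 9.0, 7.0, 5.0, 3.0, 2.0]


class TestBlur:
    def test_zero_sigma_is_identity(self, hu_volume):
        out = apply_system_blur(hu_volume, 0.0)
        assert np.array_equal(out.voxels, hu_volume.voxels)
        assert out.voxels is not hu_volume.voxels

    def test_energy_conservation(self):
        spec = PhantomSpec(n_slices=1)
        vol = render_low_contrast_module(spec)
        blurred = apply_system_blur(vol, 0.8)
        total = vol.voxels.sum() - AIR_HU * vol.voxels.size
        total_b = blurred.voxels.sum() - AIR_HU * vol.voxels.size
        assert total_b == pytest.approx(total, rel=1e-3)

    def test_gaussian_f50_closed_form_vs_numeric_fft(self):
        # independent numeric oracle: FFT of the sampled blur kernel
        sigma = 0.5
        dx = 0.01
        x = np.arange(-10, 10, dx)
        kernel = np.exp(-x ** 2 / (2 * sigma ** 2))
        spectrum = np.abs(np.fft.rfft(kernel))
        spectrum /= spectrum[0]
        freqs = np.fft.rfftfreq(x.size, d=dx)
        f50_numeric = np.interp(0.5, spectrum[::-1], freqs[::-1])
        assert gaussian_f_at(0.5, sigma) == pytest.approx(0.3748, abs=5e-4)
        assert f50_numeric == pytest.approx(gaussian_f_at(0.5, sigma), rel=1e-3)


class TestQuantumNoise:
    def test_sigma_at_reference_dose(self, rng):
        spec = PhantomSpec(n_slices=1, noise_sigma_ref_hu=10.0)
        vol = render_uniformity_module(spec)
        noisy = apply_quantum_noise(vol, spec.ref_dose, spec, seed=7)
        resid = (noisy.voxels - vol.voxels)[0, 28:228, 28:228]
        assert resid.std() == pytest.approx(10.0, abs=0.3)
        assert abs(resid.mean()) < 0.2

    def test_inverse_square_root_law(self):
        spec = PhantomSpec(n_slices=1, noise_sigma_ref_hu=10.0,
                           ref_dose=ProtocolDose(10.0, 1.0))
        vol = render_uniformity_module(spec)
        quad = apply_quantum_noise(vol, ProtocolDose(40.0, 1.0), spec, seed=9)
        resid = (quad.voxels - vol.voxels)[0, 28:228, 28:228]
        assert resid.std() == pytest.approx(5.0, abs=0.2)

    def test_determinism_and_seed_sensitivity(self):
        spec = PhantomSpec(n_slices=2)
        vol = render_uniformity_module(spec)
        a = apply_quantum_noise(vol, spec.ref_dose, spec, seed=5)
        b = apply_quantum_noise(vol, spec.ref_dose, spec, seed=5)
        c = apply_quantum_noise(vol, spec.ref_dose, spec, seed=6)
        assert np.array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            ProtocolDose(0.0, 1.0)


def test_simulate_catphan_sections_and_determinism():
    spec = PhantomSpec(matrix_size=128, pixel_spacing=1.0, n_slices=4,
                       bar_groups=[(0.2, 500.0, 4)])
    a = simulate_catphan(spec, ProtocolDose(24.7, 1.25), seed=1)
    b = simulate_catphan(spec, ProtocolDose(24.7, 1.25), seed=1)
    assert np.array_equal(a.volume.voxels, b.volume.voxels)
    assert a.volume.n_slices == 16
    assert set(a.layout["sections"]) == {
        "hu", "resolution", "low_contrast", "uniformity"}
    gt = a.ground_truth()
    assert gt["seed"] == 1 and gt["spec"]["matrix_size"] == 128
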