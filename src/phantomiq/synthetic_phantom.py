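"""Digital Catphan-style phantom generator.

Renders axial CT volumes of a cylindrical QA phantom with known ground
truth: density inserts, a four-hole geometry pattern, a wire slanted to
the axial plane (for slice-sensitivity-profile measurement), bar-pattern
resolution groups, a circular high-contrast edge (for the circular-edge
MTF), and a low-contrast disk group.  System blur is an isotropic
in-plane Gaussian, so the ground-truth MTF is the closed form
``MTF(f) = exp(-2 pi^2 sigma^2 f^2)``; quantum noise is white Gaussian
in HU with a magnitude that scales as ``1/sqrt(CTDI_vol x ST)``.

Edges are rendered with subpixel area weighting (oversampled coverage),
so an unblurred edge is a one-pixel integration ramp rather than an
aliased staircase.

Conventions: images are indexed (row, col), 0-based; polar angles are in
degrees, measured counterclockwise from the +col (3 o'clock) direction,
so 90 degrees is 12 o'clock (towards smaller row indices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import AcquisitionMeta, CTVolume, ProtocolDose

__all__ = [
    "AIR_HU",
    "LayoutError",
    "ConfigurationError",
    "PhantomSpec",
    "polar_to_rc",
    "render_hu_module",
    "render_resolution_module",
    "render_low_contrast_module",
    "render_uniformity_module",
    "apply_system_blur",
    "apply_quantum_noise",
    "gaussian_mtf",
    "gaussian_f_at",
    "simulate_catphan",
    "SimulatedPhantom",
]

AIR_HU = -1000.0


class LayoutError(ValueError):
    """A phantom feature does not fit inside the phantom body."""


class ConfigurationError(ValueError):
    """A PhantomSpec parameter is unrepresentable on the pixel grid."""


@dataclass
class PhantomSpec:
    """Parametric description of the synthetic phantom.

    Noise is specified at a reference protocol: ``noise_sigma_ref_hu``
    is the white-noise standard deviation obtained when scanning at
    ``ref_dose``; any other dose rescales it by
    ``sqrt(ref_dose.dose_product / dose.dose_product)``.

    The slice (z) sensitivity profile is Gaussian by default with FWHM
    ``z_fwhm_mm`` (defaulting to the nominal slice thickness); a
    rectangular profile of the same FWHM is available via
    ``z_profile="rect"``.
    """

    matrix_size: int = 256
    pixel_spacing: float = 0.5
    n_slices: int = 8
    slice_thickness: float = 1.25
    phantom_radius_mm: float = 45.0
    background_hu: float = 100.0
    # (polar angle deg, radial offset mm, diameter mm, HU)
    inserts: Sequence[tuple[float, float, float, float]] = field(
        default_factory=lambda: [
            (90.0, 30.0, 12.0, 990.0),   # Teflon-like
            (210.0, 30.0, 12.0, -200.0),  # LDPE-like
            (330.0, 30.0, 12.0, -1000.0),  # air
        ]
    )
    # (spatial frequency lp/mm, HU contrast, bar-gap pair count)
    bar_groups: Sequence[tuple[float, float, int]] = field(
        default_factory=lambda: [
            (0.2, 500.0, 4),
            (0.4, 500.0, 5),
            (0.6, 500.0, 6),
            (0.7, 500.0, 6),
        ]
    )
    # (diameter mm, contrast in % of background)
    low_contrast_disks: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [
            (15.0, 1.0), (9.0, 1.0), (7.0, 1.0),
            (5.0, 1.0), (3.0, 1.0), (2.0, 1.0),
        ]
    )
    wire_angle_deg: float = 23.0
    rod_spacing_mm: float = 50.0
    blur_sigma_mm: float = 0.5
    noise_sigma_ref_hu: float = 10.7
    ref_dose: ProtocolDose = field(default_factory=lambda: ProtocolDose(18.0, 2.0))
    z_profile: str = "gaussian"
    z_fwhm_mm: Optional[float] = None
    # geometry of auxiliary features
    mtf_insert_diameter_mm: float = 12.0
    mtf_insert_hu: float = 990.0
    hole_diameter_mm: float = 3.0
    wire_row_offset_mm: float = -18.0   # relative to center; negative = above
    wire_peak_hu: float = 1000.0        # peak contrast over background
    wire_sigma_row_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise ConfigurationError("pixel_spacing must be > 0")
        if self.matrix_size * self.pixel_spacing < 2 * self.phantom_radius_mm:
            raise ConfigurationError(
                "matrix_size x pixel_spacing must cover the phantom diameter"
            )
        nyquist = 1.0 / (2.0 * self.pixel_spacing)
        for f, _, _ in self.bar_groups:
            if f >= nyquist:
                raise ConfigurationError(
                    f"bar frequency {f} lp/mm not representable at "
                    f"pixel spacing {self.pixel_spacing} mm (Nyquist {nyquist})"
                )
        for angle, offset, diameter, _ in self.inserts:
            if offset + diameter / 2.0 > self.phantom_radius_mm:
                raise LayoutError(
                    f"insert at ({angle} deg, {offset} mm, d={diameter} mm) "
                    f"extends outside phantom radius {self.phantom_radius_mm} mm"
                )
        if self.z_profile not in ("gaussian", "rect"):
            raise ConfigurationError(f"unknown z profile {self.z_profile!r}")

    @property
    def z_fwhm(self) -> float:
        return self.z_fwhm_mm if self.z_fwhm_mm is not None else self.slice_thickness

    @property
    def center_rc(self) -> tuple[float, float]:
        c = (self.matrix_size - 1) / 2.0
        return (c, c)

    def slice_positions(self, z0: float = 0.0) -> np.ndarray:
        return z0 + np.arange(self.n_slices) * self.slice_thickness

    # ---- layout queries (ground truth for localization/tests) ----

    def insert_centers_rc(self) -> list[tuple[float, float]]:
        return [
            polar_to_rc(self.center_rc, a, r, self.pixel_spacing)
            for a, r, _, _ in self.inserts
        ]

    def hole_centers_rc(self) -> list[tuple[float, float]]:
        """Four hole centers (px) on a rod_spacing x rod_spacing square."""
        half = self.rod_spacing_mm / 2.0 / self.pixel_spacing
        cr, cc = self.center_rc
        return [
            (cr - half, cc - half), (cr - half, cc + half),
            (cr + half, cc - half), (cr + half, cc + half),
        ]

    def low_contrast_layout(self) -> list[dict]:
        """Disk placements: evenly spaced polar angles at 0.55 R."""
        radius = 0.55 * self.phantom_radius_mm
        n = len(self.low_contrast_disks)
        out = []
        for i, (diameter, contrast_pct) in enumerate(self.low_contrast_disks):
            angle = 90.0 - 360.0 * i / max(n, 1)
            rc = polar_to_rc(self.center_rc, angle, radius, self.pixel_spacing)
            out.append({
                "diameter_mm": diameter,
                "contrast_pct": contrast_pct,
                "center_rc": rc,
                "angle_deg": angle,
                "radius_mm": radius,
            })
        return out

    def bar_group_layout(self) -> list[dict]:
        """Bar-group rectangles: bars run along rows, pattern along cols."""
        radius = 0.55 * self.phantom_radius_mm
        n = len(self.bar_groups)
        out = []
        for i, (freq, contrast, pairs) in enumerate(self.bar_groups):
            angle = 180.0 + 360.0 * i / max(n, 1) if n > 1 else 180.0
            rc = polar_to_rc(self.center_rc, angle, radius, self.pixel_spacing)
            width_mm = pairs / freq
            height_mm = 10.0
            out.append({
                "frequency_lp_mm": freq,
                "contrast_hu": contrast,
                "pairs": pairs,
                "center_rc": rc,
                "width_px": width_mm / self.pixel_spacing,
                "height_px": height_mm / self.pixel_spacing,
            })
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ref_dose"] = {
            "ctdi_vol": self.ref_dose.ctdi_vol,
            "slice_thickness": self.ref_dose.slice_thickness,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        rd = d.get("ref_dose")
        if isinstance(rd, dict):
            d["ref_dose"] = ProtocolDose(rd["ctdi_vol"], rd["slice_thickness"])
        d["inserts"] = [tuple(t) for t in d.get("inserts", [])]
        d["bar_groups"] = [tuple(t) for t in d.get("bar_groups", [])]
        d["low_contrast_disks"] = [tuple(t) for t in d.get("low_contrast_disks", [])]
        return cls(**d)


def polar_to_rc(
    center_rc: tuple[float, float],
    angle_deg: float,
    radius_mm: float,
    pixel_spacing: float,
) -> tuple[float, float]:
    """Polar (deg CCW from +col, mm) -> (row, col) pixel coordinates."""
    th = math.radians(angle_deg)
    row = center_rc[0] - radius_mm * math.sin(th) / pixel_spacing
    col = center_rc[1] + radius_mm * math.cos(th) / pixel_spacing
    return (row, col)


# ---------------------------------------------------------------------------
# rendering primitives

def _disk_coverage(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    radius_px: float,
    oversample: int = 8,
) -> tuple[slice, slice, np.ndarray]:
    """Per-pixel area coverage of a disk, restricted to its bounding box.

    Returns (row_slice, col_slice, coverage in [0, 1]).
    """
    cr, cc = center_rc
    r0 = max(int(math.floor(cr - radius_px - 1)), 0)
    r1 = min(int(math.ceil(cr + radius_px + 2)), shape[0])
    c0 = max(int(math.floor(cc - radius_px - 1)), 0)
    c1 = min(int(math.ceil(cc + radius_px + 2)), shape[1])
    if r1 <= r0 or c1 <= c0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    rows = np.arange(r0, r1)[:, None] + sub[None, :]        # (nr, os)
    cols = np.arange(c0, c1)[:, None] + sub[None, :]        # (nc, os)
    dr2 = (rows - cr) ** 2                                   # (nr, os)
    dc2 = (cols - cc) ** 2                                   # (nc, os)
    inside = (dr2[:, None, :, None] + dc2[None, :, None, :]) <= radius_px ** 2
    cov = inside.mean(axis=(2, 3))
    return slice(r0, r1), slice(c0, c1), cov


def _composite_disk(
    img: np.ndarray,
    center_rc: tuple[float, float],
    radius_px: float,
    value: float,
    oversample: int = 8,
) -> None:
    """Paint an anti-aliased disk over ``img`` in place ("over" compositing)."""
    rs, cs, cov = _disk_coverage(img.shape, center_rc, radius_px, oversample)
    img[rs, cs] = img[rs, cs] * (1.0 - cov) + value * cov


def _base_slice(spec: PhantomSpec) -> np.ndarray:
    img = np.full((spec.matrix_size, spec.matrix_size), AIR_HU)
    _composite_disk(
        img, spec.center_rc, spec.phantom_radius_mm / spec.pixel_spacing,
        spec.background_hu,
    )
    return img


def _z_profile_value(spec: PhantomSpec, dz_mm: np.ndarray) -> np.ndarray:
    """Slice sensitivity profile, peak-normalized to 1 at dz = 0."""
    fwhm = spec.z_fwhm
    if spec.z_profile == "rect":
        return (np.abs(dz_mm) <= fwhm / 2.0).astype(float)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-(dz_mm ** 2) / (2.0 * sigma ** 2))


def _volume_from_slices(
    spec: PhantomSpec, slices: list[np.ndarray], z0: float = 0.0,
    dose: Optional[ProtocolDose] = None,
) -> CTVolume:
    meta = AcquisitionMeta(
        kvp=120.0,
        ctdi_vol=None if dose is None else dose.ctdi_vol,
        protocol_name="synthetic",
    )
    return CTVolume(
        voxels=np.stack(slices, axis=0),
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_positions=spec.slice_positions(z0),
        nominal_slice_thickness=spec.slice_thickness,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# module renderers (noiseless, blur-free)

def render_hu_module(spec: PhantomSpec) -> CTVolume:
    """Density-insert module: inserts, four-hole pattern and slanted wire.

    The wire lies in a plane parallel to (col, z), crossing the module
    mid-z at the phantom's center column, tilted ``wire_angle_deg`` from
    the axial plane: its in-plane (col) position advances by
    ``slice_spacing / tan(angle)`` per slice.  On each slice the wire
    deposits ``wire_peak_hu x SSP(z_slice - z_wire(col))`` over a narrow
    Gaussian row band, which is exactly the signal the slanted-wire SSP
    method reads out.
    """
    tan_a = math.tan(math.radians(spec.wire_angle_deg))
    if tan_a <= 0:
        raise ConfigurationError("wire angle must be in (0, 90) degrees")
    cr, cc = spec.center_rc
    zs = spec.slice_positions()
    z_mid = float(zs.mean())
    hole_r_px = spec.hole_diameter_mm / 2.0 / spec.pixel_spacing

    base = _base_slice(spec)
    for (a, r, d, hu), rc in zip(spec.inserts, spec.insert_centers_rc()):
        _composite_disk(base, rc, d / 2.0 / spec.pixel_spacing, hu)
    for rc in spec.hole_centers_rc():
        _composite_disk(base, rc, hole_r_px, AIR_HU)

    wire_row = cr + spec.wire_row_offset_mm / spec.pixel_spacing
    rows = np.arange(spec.matrix_size, dtype=float)
    row_weight = np.exp(
        -((rows - wire_row) * spec.pixel_spacing) ** 2
        / (2.0 * spec.wire_sigma_row_mm ** 2)
    )
    cols_mm = (np.arange(spec.matrix_size) - cc) * spec.pixel_spacing
    # wire only inside the body (with margin)
    half_len = 0.8 * spec.phantom_radius_mm
    in_wire = np.abs(cols_mm) <= half_len

    out = []
    for z in zs:
        img = base.copy()
        z_wire = z_mid + cols_mm * tan_a     # wire z at each column
        amp = spec.wire_peak_hu * _z_profile_value(spec, z - z_wire)
        amp = np.where(in_wire, amp, 0.0)
        img += row_weight[:, None] * amp[None, :]
        out.append(img)
    return _volume_from_slices(spec, out)


def render_resolution_module(spec: PhantomSpec) -> CTVolume:
    """Resolution module: central high-contrast disk plus bar groups."""
    img = _base_slice(spec)
    _composite_disk(
        img, spec.center_rc,
        spec.mtf_insert_diameter_mm / 2.0 / spec.pixel_spacing,
        spec.mtf_insert_hu,
    )
    os = 16
    sub = (np.arange(os) + 0.5) / os - 0.5
    for g in spec.bar_group_layout():
        freq = g["frequency_lp_mm"]
        period_px = 1.0 / freq / spec.pixel_spacing
        rc = g["center_rc"]
        h, w = g["height_px"], g["width_px"]
        r0 = int(round(rc[0] - h / 2.0))
        r1 = int(round(rc[0] + h / 2.0))
        c0 = int(math.floor(rc[1] - w / 2.0)) - 1
        c1 = int(math.ceil(rc[1] + w / 2.0)) + 1
        cols = np.arange(c0, c1)[:, None] + sub[None, :]
        phase = (cols - (rc[1] - w / 2.0)) / period_px
        in_group = (phase >= 0) & (phase < g["pairs"])
        is_bar = (np.mod(phase, 1.0) < 0.5) & in_group
        cov = is_bar.mean(axis=1)
        img[r0:r1, c0:c1] += g["contrast_hu"] * cov[None, :]
    return _volume_from_slices(spec, [img.copy() for _ in range(spec.n_slices)])


def render_low_contrast_module(spec: PhantomSpec) -> CTVolume:
    """Low-contrast module: disks at ``background x (1 + contrast%/100)``."""
    img = _base_slice(spec)
    for g in spec.low_contrast_layout():
        hu = spec.background_hu * (1.0 + g["contrast_pct"] / 100.0)
        _composite_disk(
            img, g["center_rc"], g["diameter_mm"] / 2.0 / spec.pixel_spacing, hu,
        )
    return _volume_from_slices(spec, [img.copy() for _ in range(spec.n_slices)])


def render_uniformity_module(spec: PhantomSpec) -> CTVolume:
    """Uniform body only (the uniformity/noise section)."""
    img = _base_slice(spec)
    return _volume_from_slices(spec, [img.copy() for _ in range(spec.n_slices)])


# ---------------------------------------------------------------------------
# degradation operators

def apply_system_blur(vol: CTVolume, sigma_mm: float) -> CTVolume:
    """In-plane isotropic Gaussian blur; ground-truth MTF exp(-2 pi^2 s^2 f^2)."""
    if sigma_mm < 0:
        raise ValueError("blur sigma must be >= 0")
    if sigma_mm == 0:
        return vol.with_voxels(vol.voxels.copy())
    sr = sigma_mm / vol.pixel_spacing[0]
    sc = sigma_mm / vol.pixel_spacing[1]
    blurred = ndimage.gaussian_filter(vol.voxels, sigma=(0.0, sr, sc), mode="nearest")
    return vol.with_voxels(blurred)


def noise_sigma_at(spec: PhantomSpec, dose: ProtocolDose) -> float:
    """White-noise sigma (HU) at ``dose``: quantum 1/sqrt(CTDI x ST) scaling."""
    return spec.noise_sigma_ref_hu * math.sqrt(
        spec.ref_dose.dose_product / dose.dose_product
    )


def apply_quantum_noise(
    vol: CTVolume, dose: ProtocolDose, spec: PhantomSpec, seed: int
) -> CTVolume:
    """Add zero-mean white Gaussian noise at the dose-scaled sigma."""
    sigma = noise_sigma_at(spec, dose)
    rng = np.random.default_rng(seed)
    noisy = vol.voxels + rng.normal(0.0, sigma, size=vol.shape)
    out = vol.with_voxels(noisy)
    out.meta.ctdi_vol = dose.ctdi_vol
    return out


# ---------------------------------------------------------------------------
# closed-form Gaussian MTF oracle

def gaussian_mtf(f_lp_mm: np.ndarray, sigma_mm: float) -> np.ndarray:
    """MTF of an isotropic Gaussian blur of standard deviation sigma."""
    f = np.asarray(f_lp_mm, dtype=float)
    return np.exp(-2.0 * math.pi ** 2 * sigma_mm ** 2 * f ** 2)


def gaussian_f_at(level: float, sigma_mm: float) -> float:
    """Frequency (lp/mm) where the Gaussian MTF crosses ``level``."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return math.sqrt(-math.log(level) / (2.0 * math.pi ** 2 * sigma_mm ** 2))


# ---------------------------------------------------------------------------
# composite phantom

@dataclass
class SimulatedPhantom:
    """A rendered phantom volume plus its generating ground truth."""

    volume: CTVolume
    spec: PhantomSpec
    dose: Optional[ProtocolDose]
    seed: Optional[int]
    layout: dict

    def ground_truth(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "dose": None if self.dose is None else {
                "ctdi_vol": self.dose.ctdi_vol,
                "slice_thickness": self.dose.slice_thickness,
            },
            "seed": self.seed,
            "layout": self.layout,
        }


def simulate_catphan(
    spec: Optional[PhantomSpec] = None,
    dose: Optional[ProtocolDose] = None,
    seed: Optional[int] = None,
    blur: bool = True,
) -> SimulatedPhantom:
    """Render the full four-section phantom along z.

    Sections, in z order, each ``spec.n_slices`` thick: density/geometry
    (inserts + holes + slanted wire), resolution (edge disk + bars),
    low-contrast disks, and uniformity.  Blur and (if ``dose`` and
    ``seed`` are given) quantum noise are applied to the whole stack.
    """
    spec = spec if spec is not None else PhantomSpec()
    sections = [
        ("hu", render_hu_module),
        ("resolution", render_resolution_module),
        ("low_contrast", render_low_contrast_module),
        ("uniformity", render_uniformity_module),
    ]
    slabs = []
    layout: dict = {"sections": {}, "pixel_spacing": spec.pixel_spacing}
    idx = 0
    for name, renderer in sections:
        v = renderer(spec)
        slabs.append(v.voxels)
        layout["sections"][name] = {
            "slice_start": idx,
            "slice_stop": idx + spec.n_slices,
            "center_slice": idx + spec.n_slices // 2,
        }
        idx += spec.n_slices
    voxels = np.concatenate(slabs, axis=0)
    positions = np.arange(idx) * spec.slice_thickness
    vol = CTVolume(
        voxels=voxels,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_positions=positions,
        nominal_slice_thickness=spec.slice_thickness,
        meta=AcquisitionMeta(
            kvp=120.0,
            ctdi_vol=None if dose is None else dose.ctdi_vol,
            protocol_name="synthetic-catphan",
        ),
    )
    if blur and spec.blur_sigma_mm > 0:
        vol = apply_system_blur(vol, spec.blur_sigma_mm)
    if dose is not None and seed is not None:
        vol = apply_quantum_noise(vol, dose, spec, seed)
    layout["phantom_center_rc"] = list(spec.center_rc)
    layout["insert_centers_rc"] = [list(rc) for rc in spec.insert_centers_rc()]
    layout["hole_centers_rc"] = [list(rc) for rc in spec.hole_centers_rc()]
    layout["low_contrast"] = [
        {**g, "center_rc": list(g["center_rc"])} for g in spec.low_contrast_layout()
    ]
    layout["bar_groups"] = [
        {**g, "center_rc": list(g["center_rc"])} for g in spec.bar_group_layout()
    ]
    layout["wire_row_px"] = spec.center_rc[0] + spec.wire_row_offset_mm / spec.pixel_spacing
    return SimulatedPhantom(volume=vol, spec=spec, dose=dose, seed=seed, layout=layout)
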