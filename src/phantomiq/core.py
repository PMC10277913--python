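"""Core data containers shared by every analysis module.

All internal units are Hounsfield units (HU) and millimeters.  Voxel
arrays are indexed ``(slice, row, col)``, 0-based, with axial slices
ordered by increasing table (z) position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "CTVolume",
    "ProtocolDose",
    "RoiSpec",
    "extract_roi",
]


@dataclass(frozen=True)
class ProtocolDose:
    """Dose-thickness descriptor of a scan protocol.

    Parameters
    ----------
    ctdi_vol : float
        Volume CT dose index in mGy.
    slice_thickness : float
        Reconstructed slice thickness in mm.

    The product ``ctdi_vol * slice_thickness`` governs quantum-noise
    scaling between protocols (noise ~ 1/sqrt(CTDI_vol * ST)).
    """

    ctdi_vol: float
    slice_thickness: float

    def __post_init__(self) -> None:
        if not (self.ctdi_vol > 0 and self.slice_thickness > 0):
            raise ValueError(
                f"ctdi_vol and slice_thickness must be strictly positive, "
                f"got {self.ctdi_vol} mGy, {self.slice_thickness} mm"
            )

    @property
    def dose_product(self) -> float:
        """CTDI_vol x slice-thickness product (mGy*mm)."""
        return self.ctdi_vol * self.slice_thickness


@dataclass
class AcquisitionMeta:
    """Acquisition/reconstruction metadata attached to a volume."""

    kvp: Optional[float] = None
    effective_mas: Optional[float] = None
    pitch: Optional[float] = None
    ctdi_vol: Optional[float] = None
    fov_mm: Optional[float] = None
    protocol_name: str = ""
    kernel: str = ""

    def __post_init__(self) -> None:
        if self.pitch is not None and not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.ctdi_vol is not None and not self.ctdi_vol > 0:
            raise ValueError(f"ctdi_vol must be > 0, got {self.ctdi_vol}")


@dataclass
class CTVolume:
    """A CT volume in HU with physical geometry.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        CT numbers in HU, float.
    pixel_spacing : (float, float)
        In-plane spacing (row mm, col mm).
    slice_positions : ndarray, shape (n_slices,)
        Table position of each slice in mm, strictly monotone increasing.
    nominal_slice_thickness : float
        Nominal reconstructed slice thickness in mm.
    meta : AcquisitionMeta
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_positions: np.ndarray
    nominal_slice_thickness: float
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3-D array with >= 1 slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be > 0, got {self.pixel_spacing}")
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape != (self.voxels.shape[0],):
            raise ValueError("slice_positions must have one entry per slice")
        if self.voxels.shape[0] > 1 and not np.all(np.diff(self.slice_positions) > 0):
            raise ValueError("slice_positions must be strictly increasing")
        if not self.nominal_slice_thickness > 0:
            raise ValueError("nominal_slice_thickness must be > 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slice_spacing(self) -> float:
        """Center-to-center slice spacing in mm (needs >= 2 slices)."""
        if self.n_slices < 2:
            return self.nominal_slice_thickness
        return float(np.mean(np.diff(self.slice_positions)))

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """Copy of this volume with replaced voxel data, same geometry."""
        return replace(self, voxels=np.asarray(voxels, dtype=float))


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular pixel region on one axial slice.

    ``center_rc`` is the (row, col) center in pixels (may be fractional;
    the realized window is the integer pixel block nearest the center).
    """

    slice_index: int
    center_rc: tuple[float, float]
    height_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.height_px < 2 or self.width_px < 2:
            raise ValueError("ROI sides must be >= 2 px")

    def bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open pixel bounds."""
        r0 = int(round(self.center_rc[0] - self.height_px / 2))
        c0 = int(round(self.center_rc[1] - self.width_px / 2))
        return r0, r0 + self.height_px, c0, c0 + self.width_px


def extract_roi(volume: CTVolume, roi: RoiSpec) -> np.ndarray:
    """Return the 2-D pixel block of ``roi``; raises if out of bounds."""
    if not 0 <= roi.slice_index < volume.n_slices:
        raise IndexError(f"slice index {roi.slice_index} outside volume")
    r0, r1, c0, c1 = roi.bounds()
    _, nrow, ncol = volume.shape
    if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
        raise IndexError(
            f"ROI rows [{r0},{r1}) cols [{c0},{c1}) outside image {nrow}x{ncol}"
        )
    return volume.voxels[roi.slice_index, r0:r1, c0:c1]
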