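"""Reading and writing CT volumes.

The on-disk format is a raw voxel array (``.npy``) plus a JSON geometry
and metadata sidecar.  Everything downstream works in HU and millimeters
with slices ordered by increasing table position; stored values are
converted to HU through the sidecar's rescale slope/intercept on read,
and the slice order recorded in the sidecar is re-sorted by position, so
a shuffled stack reads back identically.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import AcquisitionMeta, CTVolume

__all__ = ["read_raw_volume", "write_raw_volume", "NonUniformSpacingWarning"]

_SIDECAR_SUFFIX = ".json"


class NonUniformSpacingWarning(UserWarning):
    """Slice gaps deviate from the modal gap beyond tolerance."""


def write_raw_volume(
    volume: CTVolume,
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
    ground_truth: Optional[dict] = None,
) -> Path:
    """Write ``volume`` as ``path`` (.npy) + JSON sidecar.

    Voxels are stored as int16 HU (clipped to the representable range)
    with slope 1 / intercept 0, mirroring CT convention.  An optional
    ``ground_truth`` dict (e.g. the generating phantom spec) is embedded
    in the sidecar.
    """
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    stored = np.clip(np.rint(volume.voxels), -32768, 32767).astype(np.int16)
    np.save(path, stored)
    meta = volume.meta
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(_SIDECAR_SUFFIX)
    doc = {
        "shape": list(stored.shape),
        "dtype": "int16",
        "pixel_spacing_mm": list(volume.pixel_spacing),
        "slice_positions_mm": [float(z) for z in volume.slice_positions],
        "nominal_slice_thickness_mm": volume.nominal_slice_thickness,
        "rescale_slope": 1.0,
        "rescale_intercept": 0.0,
        "meta": {
            "kvp": meta.kvp,
            "effective_mas": meta.effective_mas,
            "pitch": meta.pitch,
            "ctdi_vol": meta.ctdi_vol,
            "fov_mm": meta.fov_mm,
            "protocol_name": meta.protocol_name,
            "kernel": meta.kernel,
        },
    }
    if ground_truth is not None:
        doc["ground_truth"] = ground_truth
    sidecar_path.write_text(json.dumps(doc, indent=1))
    return path


def read_raw_volume(
    path: Union[str, Path],
    sidecar: Optional[Union[str, Path]] = None,
    gap_tolerance: float = 0.01,
) -> CTVolume:
    """Read a raw volume + sidecar back into a :class:`CTVolume`.

    Stored values are mapped to HU via ``slope * value + intercept`` and
    slices are sorted by their recorded positions.  Non-uniform slice
    gaps (relative deviation from the mean gap above ``gap_tolerance``)
    raise a :class:`NonUniformSpacingWarning` but do not fail the read.
    """
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(_SIDECAR_SUFFIX)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sidecar_path}")
    doc = json.loads(sidecar_path.read_text())
    for key in ("pixel_spacing_mm", "slice_positions_mm"):
        if key not in doc:
            raise ValueError(f"sidecar missing required field {key!r}")
    stored = np.load(path)
    slope = float(doc.get("rescale_slope", 1.0))
    intercept = float(doc.get("rescale_intercept", 0.0))
    voxels = stored.astype(float) * slope + intercept
    if not np.all(np.isfinite(voxels)):
        raise ValueError("volume contains non-finite voxels")
    positions = np.asarray(doc["slice_positions_mm"], dtype=float)
    if positions.shape[0] != voxels.shape[0]:
        raise ValueError("slice_positions_mm length does not match slice count")
    order = np.argsort(positions)
    voxels = voxels[order]
    positions = positions[order]
    if positions.size > 2:
        gaps = np.diff(positions)
        mean_gap = gaps.mean()
        if mean_gap > 0 and np.max(np.abs(gaps - mean_gap)) > gap_tolerance * mean_gap:
            warnings.warn(
                f"non-uniform slice gaps (max deviation "
                f"{np.max(np.abs(gaps - mean_gap)):.3g} mm)",
                NonUniformSpacingWarning,
                stacklevel=2,
            )
    m = doc.get("meta", {})
    meta = AcquisitionMeta(
        kvp=m.get("kvp"),
        effective_mas=m.get("effective_mas"),
        pitch=m.get("pitch"),
        ctdi_vol=m.get("ctdi_vol"),
        fov_mm=m.get("fov_mm"),
        protocol_name=m.get("protocol_name", ""),
        kernel=m.get("kernel", ""),
    )
    thickness = float(
        doc.get("nominal_slice_thickness_mm")
        or (np.diff(positions).mean() if positions.size > 1 else 1.0)
    )
    return CTVolume(
        voxels=voxels,
        pixel_spacing=tuple(float(s) for s in doc["pixel_spacing_mm"]),
        slice_positions=positions,
        nominal_slice_thickness=thickness,
        meta=meta,
    )


def read_ground_truth(path: Union[str, Path]) -> Optional[dict]:
    """Ground-truth block from a volume's sidecar, if present."""
    path = Path(path)
    sidecar_path = path.with_suffix(_SIDECAR_SUFFIX) if path.suffix == ".npy" else path
    doc = json.loads(Path(sidecar_path).read_text())
    return doc.get("ground_truth")
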