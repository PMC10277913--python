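"""Contrast-to-noise ratio and low-contrast detectability.

CNR between a feature ROI (A) and a background ROI (B):

    CNR = |mean_A - mean_B| / sigma_B

averaged over the nearest five slices by default.  The scaled CNR
replaces sigma_B with the dose-scaled noise, i.e. divides the CNR by
the protocol scale factor.  Visual low-contrast scoring is replaced by
a quantitative Rose-type criterion: a disk counts as visible when
``CNR * sqrt(disk area in px) >= k`` (default k = 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import CTVolume, RoiSpec, extract_roi

__all__ = [
    "CnrResult",
    "DegenerateNoiseError",
    "cnr",
    "cnr_averaged",
    "scaled_cnr",
    "smallest_visible_disk",
    "NONE_VISIBLE",
]

NONE_VISIBLE = float("inf")   # sentinel: no disk passes the criterion


class DegenerateNoiseError(ValueError):
    """sigma_B <= 0: CNR is undefined (e.g. a noiseless render)."""


@dataclass
class CnrResult:
    mean_a: float
    mean_b: float
    sigma_b: float
    cnr: float
    cnr_scaled: Optional[float] = None
    n_slices_averaged: int = 1


def cnr(mean_a: float, mean_b: float, sigma_b: float) -> float:
    """|mean_A - mean_B| / sigma_B."""
    if sigma_b <= 0:
        raise DegenerateNoiseError(f"sigma_B must be > 0, got {sigma_b}")
    return abs(mean_a - mean_b) / sigma_b


def scaled_cnr(cnr_value: float, sigma_b: float, sigma_b_scaled: float) -> float:
    """CNR with the noise replaced by the scaled noise: CNR * s_B / s_B_scaled."""
    if sigma_b <= 0 or sigma_b_scaled <= 0:
        raise DegenerateNoiseError("noise values must be > 0")
    return cnr_value * sigma_b / sigma_b_scaled


def cnr_averaged(
    volume: CTVolume,
    roi_a: RoiSpec,
    roi_b: RoiSpec,
    n_slices: int = 5,
) -> CnrResult:
    """Per-slice CNR on a window of ``n_slices`` centered on the ROI slice.

    The window is truncated at the volume edge; the number of slices
    actually averaged is recorded.  The reported means/sigma are the
    averages of the per-slice values.
    """
    center = roi_a.slice_index
    half = n_slices // 2
    lo = max(center - half, 0)
    hi = min(lo + n_slices, volume.n_slices)
    lo = max(hi - n_slices, 0)
    per_slice = []
    for k in range(lo, hi):
        a = extract_roi(volume, RoiSpec(k, roi_a.center_rc, roi_a.height_px, roi_a.width_px))
        b = extract_roi(volume, RoiSpec(k, roi_b.center_rc, roi_b.height_px, roi_b.width_px))
        sb = float(b.std(ddof=1))
        per_slice.append((float(a.mean()), float(b.mean()), sb, cnr(a.mean(), b.mean(), sb)))
    arr = np.asarray(per_slice)
    return CnrResult(
        mean_a=float(arr[:, 0].mean()),
        mean_b=float(arr[:, 1].mean()),
        sigma_b=float(arr[:, 2].mean()),
        cnr=float(arr[:, 3].mean()),
        n_slices_averaged=len(per_slice),
    )


def smallest_visible_disk(
    volume: CTVolume,
    disk_set: Sequence[tuple[float, RoiSpec, RoiSpec]],
    criterion_k: float = 3.0,
    pixel_spacing: Optional[float] = None,
    n_slices: int = 5,
) -> float:
    """Smallest disk diameter passing the Rose-type detectability test.

    ``disk_set`` holds (diameter mm, ROI_A on the disk, ROI_B background)
    triples.  A disk is "visible" when ``CNR * sqrt(area_px) >=
    criterion_k`` with area the disk area in pixels, and the measured
    contrast is statistically significant (>= 3 standard errors of the
    ROI mean difference) — without the significance gate, estimator
    noise makes zero-contrast disks "visible" by chance.  Returns the
    smallest passing diameter in mm, or :data:`NONE_VISIBLE` when no
    disk passes.
    """
    spacing = pixel_spacing if pixel_spacing is not None else volume.pixel_spacing[0]
    visible = []
    for diameter_mm, roi_a, roi_b in disk_set:
        try:
            res = cnr_averaged(volume, roi_a, roi_b, n_slices=n_slices)
            n_a = roi_a.height_px * roi_a.width_px
            n_b = roi_b.height_px * roi_b.width_px
            se = res.sigma_b * math.sqrt(
                (1.0 / n_a + 1.0 / n_b) / res.n_slices_averaged)
            if abs(res.mean_a - res.mean_b) < 3.0 * se:
                continue
            index = res.cnr * math.sqrt(math.pi) * (diameter_mm / 2.0 / spacing)
        except DegenerateNoiseError:
            # noiseless render: CNR is infinite for any nonzero contrast
            a = extract_roi(volume, roi_a)
            b = extract_roi(volume, roi_b)
            index = math.inf if a.mean() != b.mean() else 0.0
        if index >= criterion_k:
            visible.append(diameter_mm)
    return min(visible) if visible else NONE_VISIBLE
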