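"""Semi-automatic phantom and feature localization.

Defaults are derived from image geometry (threshold the body, take its
centroid, place ROIs at fixed fractions of the body radius); every
placement can be overridden from the run config, which is what makes the
pipeline "semi"-automatic rather than blind.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import CTVolume, RoiSpec
from .synthetic_phantom import polar_to_rc

__all__ = [
    "PhantomNotFoundError",
    "find_phantom_center",
    "body_radius_px",
    "locate_insert",
    "place_uniformity_rois",
]


class PhantomNotFoundError(RuntimeError):
    """No phantom body / feature found where one was expected."""


def _body_mask(slice_image: np.ndarray, body_hu_threshold: float) -> np.ndarray:
    mask = np.asarray(slice_image) > body_hu_threshold
    if not mask.any():
        raise PhantomNotFoundError(
            f"no pixels above {body_hu_threshold} HU in slice"
        )
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def find_phantom_center(
    slice_image: np.ndarray, body_hu_threshold: float = -300.0
) -> tuple[float, float]:
    """Subpixel centroid (row, col) of the dominant thresholded body."""
    mask = _body_mask(slice_image, body_hu_threshold)
    r, c = ndimage.center_of_mass(mask)
    return (float(r), float(c))


def body_radius_px(
    slice_image: np.ndarray, body_hu_threshold: float = -300.0
) -> float:
    """Equivalent-disk radius (px) of the thresholded body mask."""
    mask = _body_mask(slice_image, body_hu_threshold)
    return float(math.sqrt(mask.sum() / math.pi))


def locate_insert(
    slice_image: np.ndarray,
    phantom_center: tuple[float, float],
    expected_polar: tuple[float, float],
    search_radius_mm: float,
    pixel_spacing: float,
    min_contrast_hu: float = 5.0,
) -> tuple[float, float]:
    """Refine an insert center near its expected polar position.

    Computes the contrast-weighted centroid of ``|HU - local median|``
    inside a square window of half-size ``search_radius_mm`` around the
    expected (angle deg, radius mm) position.  Raises if the window
    holds no contrast above ``min_contrast_hu``.
    """
    img = np.asarray(slice_image, dtype=float)
    angle_deg, radius_mm = expected_polar
    er, ec = polar_to_rc(phantom_center, angle_deg, radius_mm, pixel_spacing)
    half = max(int(round(search_radius_mm / pixel_spacing)), 1)
    r0 = max(int(round(er)) - half, 0)
    r1 = min(int(round(er)) + half + 1, img.shape[0])
    c0 = max(int(round(ec)) - half, 0)
    c1 = min(int(round(ec)) + half + 1, img.shape[1])
    window = img[r0:r1, c0:c1]
    if window.size == 0:
        raise PhantomNotFoundError("search window outside image")
    weight = np.abs(window - np.median(window))
    if weight.max() < min_contrast_hu:
        raise PhantomNotFoundError(
            f"no contrast above {min_contrast_hu} HU near "
            f"({angle_deg} deg, {radius_mm} mm)"
        )
    rr, cc = np.mgrid[r0:r1, c0:c1]
    total = weight.sum()
    return (float((weight * rr).sum() / total), float((weight * cc).sum() / total))


def place_uniformity_rois(
    volume: CTVolume,
    slice_index: int,
    roi_size_px: int = 20,
    peripheral_offset_fraction: float = 0.7,
    body_hu_threshold: float = -300.0,
    center_override: Optional[tuple[float, float]] = None,
) -> list[RoiSpec]:
    """One central + four peripheral ROIs at 12/3/6/9 o'clock.

    Peripheral ROIs sit at ``peripheral_offset_fraction`` of the body
    radius; the default 0.7 clears the edge rolloff while staying in the
    uniform region.  Returned order: center, 12, 3, 6, 9 o'clock.
    """
    if not 0 < peripheral_offset_fraction < 1:
        raise ValueError(
            f"peripheral_offset_fraction must be in (0, 1), "
            f"got {peripheral_offset_fraction}"
        )
    img = volume.voxels[slice_index]
    if center_override is not None:
        center = center_override
        radius = body_radius_px(img, body_hu_threshold)
    else:
        center = find_phantom_center(img, body_hu_threshold)
        radius = body_radius_px(img, body_hu_threshold)
    offset = peripheral_offset_fraction * radius
    cr, cc = center
    placements = [
        (cr, cc),                   # center
        (cr - offset, cc),          # 12 o'clock
        (cr, cc + offset),          # 3 o'clock
        (cr + offset, cc),          # 6 o'clock
        (cr, cc - offset),          # 9 o'clock
    ]
    rois = [
        RoiSpec(slice_index, rc, roi_size_px, roi_size_px) for rc in placements
    ]
    _, nrow, ncol = volume.shape
    for roi in rois:
        r0, r1, c0, c1 = roi.bounds()
        if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
            raise PhantomNotFoundError("uniformity ROI falls outside the image")
    return rois
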