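"""CT-number accuracy of density inserts and four-rod geometric accuracy.

Insert HU is read as the mean/std of a small (default 6x6 px) square
ROI at each insert center and checked against manufacturer reference
ranges supplied by configuration (never hard-coded).  Geometric
accuracy is the agreement of the horizontal and vertical distances
between four low-HU holes with their nominal 50 mm spacing, using
subpixel contrast-weighted centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import CTVolume, RoiSpec
from .uniformity_noise import roi_stats

__all__ = [
    "InsertReading",
    "GeometryResult",
    "HoleNotFoundError",
    "measure_insert_hu",
    "measure_rod_distances",
]


class HoleNotFoundError(RuntimeError):
    """A rod hole could not be localized in its search window."""


@dataclass
class InsertReading:
    name: str
    reference_range: Optional[tuple[float, float]]
    mean: float
    std: float
    deviation_from_range: Optional[float]   # 0 when inside the range


@dataclass
class GeometryResult:
    hole_centers_mm: list[tuple[float, float]]       # (row mm, col mm)
    pairwise_distances: dict[str, float]             # mm, adjacent pairs
    max_abs_deviation: float                         # mm from nominal


def measure_insert_hu(
    volume: CTVolume,
    insert_centers: Sequence[tuple[str, tuple[float, float]]],
    slice_index: int,
    roi_px: int = 6,
    reference_ranges: Optional[dict[str, tuple[float, float]]] = None,
) -> list[InsertReading]:
    """Mean/std per insert with optional range check.

    ``deviation_from_range`` is ``max(low - mean, mean - high, 0)`` —
    zero inside the range, the overshoot in HU outside — or ``None``
    when no range is configured for that insert.
    """
    reference_ranges = reference_ranges or {}
    out = []
    for name, center in insert_centers:
        mean, std = roi_stats(volume, RoiSpec(slice_index, tuple(center), roi_px, roi_px))
        rng = reference_ranges.get(name)
        dev = None
        if rng is not None:
            low, high = rng
            dev = max(low - mean, mean - high, 0.0)
        out.append(InsertReading(name, rng, mean, std, dev))
    return out


def _hole_centroid(
    img: np.ndarray,
    approx_rc: tuple[float, float],
    window_px: int,
    min_depth_hu: float,
) -> tuple[float, float]:
    r0 = max(int(round(approx_rc[0])) - window_px, 0)
    r1 = min(int(round(approx_rc[0])) + window_px + 1, img.shape[0])
    c0 = max(int(round(approx_rc[1])) - window_px, 0)
    c1 = min(int(round(approx_rc[1])) + window_px + 1, img.shape[1])
    window = img[r0:r1, c0:c1]
    background = np.median(window)
    depth = np.clip(background - window, 0.0, None)   # holes are low HU
    if depth.max() < min_depth_hu:
        raise HoleNotFoundError(
            f"no hole deeper than {min_depth_hu} HU near {approx_rc}"
        )
    rr, cc = np.mgrid[r0:r1, c0:c1]
    total = depth.sum()
    return (float((depth * rr).sum() / total), float((depth * cc).sum() / total))


def measure_rod_distances(
    slice_image: np.ndarray,
    approx_centers: Sequence[tuple[float, float]],
    pixel_spacing: tuple[float, float],
    nominal_mm: float = 50.0,
    window_mm: float = 6.0,
    min_depth_hu: float = 100.0,
) -> GeometryResult:
    """Subpixel hole centroids and adjacent-pair distances vs nominal.

    The four holes are assumed to sit near the corners of a square;
    distances are computed for the two horizontal (top, bottom) and two
    vertical (left, right) adjacent pairs, in physical mm.
    """
    if len(approx_centers) != 4:
        raise ValueError(f"expected 4 approximate hole centers, got {len(approx_centers)}")
    img = np.asarray(slice_image, dtype=float)
    # window_mm is the full window width; the centroid search uses +/- half
    window_px = max(int(round(window_mm / 2.0 / min(pixel_spacing))), 2)
    centers_px = [
        _hole_centroid(img, rc, window_px, min_depth_hu) for rc in approx_centers
    ]
    sr, sc = pixel_spacing
    centers_mm = [(r * sr, c * sc) for r, c in centers_px]
    # order corners: top pair = two smallest rows, each pair sorted by col
    by_row = sorted(centers_mm, key=lambda p: p[0])
    top = sorted(by_row[:2], key=lambda p: p[1])
    bottom = sorted(by_row[2:], key=lambda p: p[1])
    tl, tr = top
    bl, br = bottom

    def dist(a, b):
        return math.hypot(a[0] - b[0], a[1] - b[1])

    distances = {
        "top_horizontal": dist(tl, tr),
        "bottom_horizontal": dist(bl, br),
        "left_vertical": dist(tl, bl),
        "right_vertical": dist(tr, br),
    }
    max_dev = max(abs(d - nominal_mm) for d in distances.values())
    return GeometryResult(
        hole_centers_mm=[tl, tr, bl, br],
        pairwise_distances=distances,
        max_abs_deviation=max_dev,
    )
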