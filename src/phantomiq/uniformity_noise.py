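"""Image uniformity, noise, and dose-scaled noise.

Uniformity is the maximum absolute difference between the central-ROI
mean HU and the four peripheral-ROI means.  Noise is the sample
standard deviation of HU within an ROI; the headline value is the
central ROI's.  The scaled noise rescales a measurement to a reference
protocol through the square root of the CTDI_vol x slice-thickness
product ratio, isolating hardware/algorithm differences from dose:

    sigma_scaled = sigma * sqrt((CTDI*ST)_test / (CTDI*ST)_ref)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import CTVolume, ProtocolDose, RoiSpec, extract_roi

__all__ = ["UniformityResult", "roi_stats", "uniformity", "scaled_noise",
           "analyze_uniformity"]


@dataclass
class UniformityResult:
    center_mean: float
    peripheral_means: tuple[float, float, float, float]
    uniformity_hu: float
    roi_stds: tuple[float, float, float, float, float]
    noise_hu: float
    scaled_noise_hu: Optional[float] = None


def roi_stats(volume: CTVolume, roi: RoiSpec) -> tuple[float, float]:
    """(mean HU, sample std HU) of the ROI pixels; raises if out of bounds."""
    block = extract_roi(volume, roi)
    return float(block.mean()), float(block.std(ddof=1))


def uniformity(center_mean: float, peripheral_means: Sequence[float]) -> float:
    """max_i |center - peripheral_i| in HU."""
    return float(max(abs(center_mean - p) for p in peripheral_means))


def scaled_noise(sigma: float, this: ProtocolDose, ref: ProtocolDose) -> float:
    """Rescale a measured noise to the reference protocol's dose product."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return sigma * math.sqrt(this.dose_product / ref.dose_product)


def analyze_uniformity(
    volume: CTVolume,
    rois: Sequence[RoiSpec],
    this_dose: Optional[ProtocolDose] = None,
    ref_dose: Optional[ProtocolDose] = None,
) -> UniformityResult:
    """Full uniformity/noise readout on 5 ROIs (center, then 4 peripheral).

    The headline noise is the central-ROI std; the scaled noise is added
    when both protocols are supplied (the reference pairing is always an
    explicit config choice, never inferred).
    """
    if len(rois) != 5:
        raise ValueError(f"expected 5 ROIs (center + 4 peripheral), got {len(rois)}")
    stats = [roi_stats(volume, r) for r in rois]
    center_mean = stats[0][0]
    periph = tuple(s[0] for s in stats[1:])
    stds = tuple(s[1] for s in stats)
    noise = stds[0]
    scaled = (
        scaled_noise(noise, this_dose, ref_dose)
        if this_dose is not None and ref_dose is not None
        else None
    )
    return UniformityResult(
        center_mean=center_mean,
        peripheral_means=periph,
        uniformity_hu=uniformity(center_mean, periph),
        roi_stds=stds,
        noise_hu=noise,
        scaled_noise_hu=scaled,
    )
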