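"""CTDI_vol from pencil-chamber readings.

Readings are CTDI_100 values (already length-normalized, in mGy) taken
at the central hole and a peripheral (12 o'clock) hole of the CTDI
phantom.  The weighted dose index is

    CTDI_w   = (1/3) * mean(central) + (2/3) * mean(peripheral)
    CTDI_vol = CTDI_w / pitch

Repeatability is reported as the coefficient of variation (std/mean)
per position; with a single reading the CoV is absent, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["CtdiMeasurement", "CtdiResult", "ctdi_vol"]


@dataclass
class CtdiMeasurement:
    central_readings: Sequence[float]
    peripheral_readings: Sequence[float]
    pitch: float
    nominal_ctdi_vol: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.central_readings) < 1 or len(self.peripheral_readings) < 1:
            raise ValueError("need at least one central and one peripheral reading")
        if any(r <= 0 for r in self.central_readings) or any(
            r <= 0 for r in self.peripheral_readings
        ):
            raise ValueError("dose readings must be strictly positive")
        if not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")


@dataclass
class CtdiResult:
    ctdi_w: float
    ctdi_vol: float
    cov_central: Optional[float]
    cov_peripheral: Optional[float]
    pct_deviation: Optional[float]


def _cov(readings: Sequence[float]) -> Optional[float]:
    # population std: the CoV describes the observed repeat spread itself
    if len(readings) < 2:
        return None
    arr = np.asarray(readings, dtype=float)
    return float(arr.std(ddof=0) / arr.mean())


def ctdi_vol(meas: CtdiMeasurement) -> CtdiResult:
    """Weighted 1/3-central + 2/3-peripheral dose index divided by pitch."""
    central = float(np.mean(meas.central_readings))
    peripheral = float(np.mean(meas.peripheral_readings))
    w = central / 3.0 + 2.0 * peripheral / 3.0
    vol = w / meas.pitch
    pct = (
        100.0 * (vol - meas.nominal_ctdi_vol) / meas.nominal_ctdi_vol
        if meas.nominal_ctdi_vol is not None
        else None
    )
    return CtdiResult(
        ctdi_w=w,
        ctdi_vol=vol,
        cov_central=_cov(meas.central_readings),
        cov_peripheral=_cov(meas.peripheral_readings),
        pct_deviation=pct,
    )
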