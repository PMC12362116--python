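"""Photometric and angular unit conversions for mesopic microperimetry.

Microperimetry reports sensitivity as decibels of *attenuation* relative to
the brightest stimulus the device can present: 0 dB means the participant
only responded to the maximum luminance, and each +10 dB corresponds to a
tenfold dimming of the stimulus.  For the device emulated here the maximum
stimulus is 127 cd/m^2 and the dynamic range is 0-20 dB, so 20 dB
corresponds to 1.27 cd/m^2.

Retinal positions and distances are expressed in degrees of visual angle.
A single retinal scale factor (micrometers per degree) converts between
angular and physical retinal distance; the default of 290 um/deg is
consistent with the study conventions this package emulates (2 deg ~ 580 um,
10 deg ~ 2900 um).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitScale",
    "DEFAULT_SCALE",
    "db_to_luminance",
    "luminance_to_db",
    "deg_to_um",
    "um_to_deg",
]


@dataclass(frozen=True)
class UnitScale:
    """Device and retinal scale constants.

    Parameters
    ----------
    um_per_deg
        Micrometers of retinal distance per degree of visual angle.
    max_luminance_cdm2
        Luminance of the 0 dB (maximum intensity) stimulus, in cd/m^2.
    db_range
        Inclusive (low, high) attainable sensitivity range in dB.
    """

    um_per_deg: float = 290.0
    max_luminance_cdm2: float = 127.0
    db_range: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.um_per_deg <= 0:
            raise ValueError("um_per_deg must be positive")
        if self.max_luminance_cdm2 <= 0:
            raise ValueError("max_luminance_cdm2 must be positive")
        lo, hi = self.db_range
        if not lo < hi:
            raise ValueError("db_range lower bound must be below upper bound")


DEFAULT_SCALE = UnitScale()


def db_to_luminance(db, scale: UnitScale = DEFAULT_SCALE):
    """Convert a sensitivity (dB attenuation) to stimulus luminance in cd/m^2.

    ``luminance = max_luminance * 10**(-db/10)``; e.g. 10 dB -> 12.7 cd/m^2
    with the default scale.  Raises ``ValueError`` for values outside the
    device's dB range.
    """
    db = np.asarray(db, dtype=float)
    lo, hi = scale.db_range
    if np.any(db < lo) or np.any(db > hi):
        raise ValueError(f"dB value outside attainable range [{lo}, {hi}]")
    out = scale.max_luminance_cdm2 * 10.0 ** (-db / 10.0)
    return float(out) if out.ndim == 0 else out


def luminance_to_db(luminance, scale: UnitScale = DEFAULT_SCALE):
    """Inverse of :func:`db_to_luminance` (luminance in cd/m^2 to dB)."""
    lum = np.asarray(luminance, dtype=float)
    if np.any(lum <= 0):
        raise ValueError("luminance must be positive")
    out = 10.0 * np.log10(scale.max_luminance_cdm2 / lum)
    lo, hi = scale.db_range
    if np.any(out < lo - 1e-9) or np.any(out > hi + 1e-9):
        raise ValueError(f"luminance corresponds to dB outside [{lo}, {hi}]")
    return float(out) if out.ndim == 0 else out


def deg_to_um(deg, scale: UnitScale = DEFAULT_SCALE):
    """Convert degrees of visual angle to micrometers of retinal distance."""
    deg = np.asarray(deg, dtype=float)
    if np.any(deg < 0):
        raise ValueError("angular distance must be non-negative")
    out = deg * scale.um_per_deg
    return float(out) if out.ndim == 0 else out


def um_to_deg(um, scale: UnitScale = DEFAULT_SCALE):
    """Convert micrometers of retinal distance to degrees of visual angle."""
    um = np.asarray(um, dtype=float)
    if np.any(um < 0):
        raise ValueError("retinal distance must be non-negative")
    out = um / scale.um_per_deg
    return float(out) if out.ndim == 0 else out
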