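"""Light: PAR conditioning, shortwave conversion, attenuation, day length.

Covers the detection-limit floor of the moored PAR sensor, conversion of
reanalysis surface shortwave to PAR, clear-water exponential attenuation,
the mixed-layer-averaged PAR experienced by a phytoplankton cell stirred
through the layer, a chlorophyll power-law euphotic depth, and the sunrise
equation for polar day/night.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PAR_FLOOR = 10.0 ** (-1.32)  # umol m-2 s-1, sensor detection limit constant
W_TO_PAR = 2.1  # (umol m-2 s-1) per (W m-2), fixed spectral distribution
KD_CLEAR = 0.02  # m-1, spectrally averaged clear-water attenuation


@dataclass
class LightParams:
    """Tunable light-model constants (defaults as used throughout)."""

    kd: float = KD_CLEAR
    par_floor: float = PAR_FLOOR
    w_to_par: float = W_TO_PAR
    eu_a: float = 34.0  # m, euphotic power-law scale
    eu_b: float = -0.39  # dimensionless exponent (negative: more chl, shallower)

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.w_to_par <= 0:
            raise ValueError("kd and w_to_par must be positive")
        if self.eu_b >= 0:
            raise ValueError("euphotic exponent must be negative")


def floor_detection_limit(par, par_floor: float = PAR_FLOOR):
    """Clamp PAR below the sensor detection limit to the limit constant.

    Returns ``(floored, was_floored)``; values strictly below the floor are
    raised to it and marked.
    """
    par = np.asarray(par, dtype=float)
    flagged = par < par_floor
    out = np.where(flagged, par_floor, par)
    if out.ndim == 0:
        return float(out), bool(flagged)
    return out, flagged


def shortwave_to_par(ssr, w_to_par: float = W_TO_PAR):
    """Convert surface shortwave irradiance (W m-2) to PAR (umol m-2 s-1)."""
    ssr = np.asarray(ssr, dtype=float)
    if np.any(ssr < 0):
        raise ValueError("shortwave irradiance must be >= 0")
    out = w_to_par * ssr
    return float(out) if out.ndim == 0 else out


def par_at_depth(par_surf, z, kd: float = KD_CLEAR):
    """PAR at depth z (m) under constant exponential extinction."""
    if np.any(np.asarray(z) < 0):
        raise ValueError("depth must be >= 0")
    out = np.asarray(par_surf, dtype=float) * np.exp(-kd * np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def par_available(par_surf, mld, kd: float = KD_CLEAR):
    """Mixed-layer average PAR for a cell stirred through the layer.

    Depth average of the exponentially extinguished surface PAR over
    [0, MLD]: ``par_surf * (1 - exp(-kd*MLD)) / (kd*MLD)``, with the limit
    ``par_surf`` as MLD -> 0.
    """
    par_surf = np.asarray(par_surf, dtype=float)
    mld = np.asarray(mld, dtype=float)
    if np.any(mld < 0):
        raise ValueError("MLD must be >= 0")
    x = kd * mld
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(x > 1e-12, -np.expm1(-x) / np.where(x > 1e-12, x, 1.0), 1.0)
    out = par_surf * factor
    return float(out) if out.ndim == 0 else out


def euphotic_depth(chl, eu_a: float = 34.0, eu_b: float = -0.39):
    """Euphotic depth (m) from average chlorophyll (ug l-1), power law.

    ``z_eu = eu_a * chl**eu_b``. The default coefficients reproduce a 20 m
    euphotic depth at 4 ug/l and ~16 m at 7 ug/l, the regime of interest
    here; they are a stand-in for published case-1-water relations and are
    exposed for recalibration.
    """
    chl = np.asarray(chl, dtype=float)
    if np.any(chl <= 0):
        raise ValueError("chlorophyll must be > 0")
    out = eu_a * chl**eu_b
    return float(out) if out.ndim == 0 else out


def _solar_declination_deg(date) -> float:
    """Low-precision solar declination (degrees) for a calendar date."""
    doy = pd.Timestamp(date).dayofyear
    return -23.44 * math.cos(2.0 * math.pi * (doy + 10) / 365.25)


def day_length(latitude: float, date) -> float:
    """Hours of sun above the horizon from the sunrise equation.

    ``cos(omega0) = -tan(lat) * tan(decl)``; day length is ``2*omega0`` in
    hours, clamped to [0, 24] (polar night / polar day). Atmospheric
    refraction is ignored.
    """
    if abs(latitude) > 90:
        raise ValueError("latitude outside [-90, 90]")
    decl = math.radians(_solar_declination_deg(date))
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    if x <= -1.0:
        return 24.0
    if x >= 1.0:
        return 0.0
    omega0 = math.acos(x)
    return 24.0 * omega0 / math.pi


def polar_day_night(latitude: float, dates) -> pd.Series:
    """Day length (h) for a sequence of dates at one latitude."""
    idx = pd.DatetimeIndex(dates)
    return pd.Series([day_length(latitude, d) for d in idx], index=idx, name="day_length_h")
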