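"""Seawater equation-of-state quantities for moored T/S/O2 sensors.

Implements the UNESCO 1983 (EOS-80) density polynomial and adiabatic lapse
rate, potential density, the two-sensor buoyancy frequency N^2 with its
thermal/haline decomposition, apparent oxygen utilization against the
Garcia & Gordon (1992) solubility fit, and a sea-ice meltwater fraction
from a two-endmember salinity balance.

Practical salinity is used throughout, matching what the conductivity
sensors report. The EOS family is declared in :data:`CONFIG` for
provenance; only EOS-80 is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

G = 9.81  # m s-2

CONFIG = {
    "eos": "EOS-80 (UNESCO 1983)",
    "o2_solubility": "Garcia & Gordon (1992), Benson-Krause fit, ml/l scale",
    "s_source": 35.1,  # Atlantic Water endmember salinity
    "s_ice": 8.0,  # bulk sea-ice salinity endmember
}


@dataclass(frozen=True)
class TSPoint:
    """In-situ temperature (degC), practical salinity, pressure (dbar)."""

    temperature: float
    salinity: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.salinity <= 42.0):
            raise ValueError(f"salinity {self.salinity} outside [0, 42]")
        if not (-3.0 <= self.temperature <= 40.0):
            raise ValueError(f"temperature {self.temperature} outside [-3, 40]")
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0 dbar")


@dataclass(frozen=True)
class StratificationSample:
    """Buoyancy frequency between two sensors and its T/S decomposition.

    ``n2`` is the total buoyancy frequency squared (s-2, positive when
    stably stratified); ``n2_t``/``n2_s`` the thermal and haline parts.
    Their sum matches ``n2`` up to equation-of-state nonlinearity (<~5 %
    for moderate differences).
    """

    n2: float
    n2_t: float
    n2_s: float
    dz: float
    rho0: float
    alpha: float
    beta: float
    g: float = G


# --------------------------------------------------------------------------
# EOS-80 density (UNESCO 1983 polynomial)
# --------------------------------------------------------------------------

def _density_atm(s, t):
    """rho(S, T, p=0) in kg m-3 (one-atmosphere EOS-80 polynomial)."""
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def _secant_bulk_modulus(s, t, p_bar):
    kw = (
        19652.21
        + 148.4206 * t
        - 2.327105 * t**2
        + 1.360477e-2 * t**3
        - 5.155288e-5 * t**4
    )
    k0 = (
        kw
        + s * (54.6746 - 0.603459 * t + 1.09987e-2 * t**2 - 6.1670e-5 * t**3)
        + s**1.5 * (7.944e-2 + 1.6483e-2 * t - 5.3009e-4 * t**2)
    )
    aw = 3.239908 + 1.43713e-3 * t + 1.16092e-4 * t**2 - 5.77905e-7 * t**3
    a = (
        aw
        + s * (2.2838e-3 - 1.0981e-5 * t - 1.6078e-6 * t**2)
        + 1.91075e-4 * s**1.5
    )
    bw = 8.50935e-5 - 6.12293e-6 * t + 5.2787e-8 * t**2
    b = bw + s * (-9.9348e-7 + 2.0816e-8 * t + 9.1697e-10 * t**2)
    return k0 + a * p_bar + b * p_bar**2


def density(s, t, p_dbar=0.0):
    """In-situ density rho(S, T, p) in kg m-3 (EOS-80)."""
    p_bar = np.asarray(p_dbar, dtype=float) / 10.0
    rho0 = _density_atm(np.asarray(s, dtype=float), np.asarray(t, dtype=float))
    out = np.where(p_bar == 0, rho0, rho0 / (1.0 - p_bar / _secant_bulk_modulus(s, t, p_bar)))
    return out if out.ndim else float(out)


def _adiabatic_lapse(s, t, p):
    """Adiabatic lapse rate (degC/dbar), UNESCO 1983."""
    ds = s - 35.0
    return (
        3.5803e-5
        + 8.5258e-6 * t
        - 6.836e-8 * t**2
        + 6.6228e-10 * t**3
        + (1.8932e-6 - 4.2393e-8 * t) * ds
        + (
            1.8741e-8
            - 6.7795e-10 * t
            + 8.733e-12 * t**2
            - 5.4481e-14 * t**3
        )
        * p
        + (-1.1351e-10 + 2.7759e-12 * t) * ds * p
        + (-4.6206e-13 + 1.8676e-14 * t - 2.1687e-16 * t**2) * p**2
    )


def potential_temperature(s, t, p_dbar, reference_pressure=0.0):
    """Potential temperature via the Fofonoff 4th-order Runge-Kutta descent."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p_dbar, dtype=float)
    sq2 = np.sqrt(2.0)
    dp = np.asarray(reference_pressure, dtype=float) - p

    dth = dp * _adiabatic_lapse(s, t, p)
    th = t + 0.5 * dth
    q = dth
    dth = dp * _adiabatic_lapse(s, th, p + 0.5 * dp)
    th = th + (1 - 1 / sq2) * (dth - q)
    q = (2 - sq2) * dth + (-2 + 3 / sq2) * q
    dth = dp * _adiabatic_lapse(s, th, p + 0.5 * dp)
    th = th + (1 + 1 / sq2) * (dth - q)
    q = (2 + sq2) * dth + (-2 - 3 / sq2) * q
    dth = dp * _adiabatic_lapse(s, th, p + dp)
    out = th + (dth - 2 * q) / 6.0
    return out if out.ndim else float(out)


def potential_density(point: TSPoint, reference_pressure: float = 0.0) -> float:
    """Potential density (kg m-3) referenced to ``reference_pressure`` dbar."""
    theta = potential_temperature(
        point.salinity, point.temperature, point.pressure, reference_pressure
    )
    return float(density(point.salinity, theta, reference_pressure))


def expansion_contraction(s, t, p_dbar=0.0, reference_pressure=0.0, eps=1e-3):
    """Thermal expansion alpha (1/degC) and haline contraction beta (1/psu).

    Centered finite differences of potential density about (S, T), the
    standard route when only a polynomial EOS is available.
    """

    def sig(ss, tt):
        th = potential_temperature(ss, tt, p_dbar, reference_pressure)
        return density(ss, th, reference_pressure)

    rho = sig(s, t)
    alpha = -(sig(s, t + eps) - sig(s, t - eps)) / (2 * eps) / rho
    beta = (sig(s + eps, t) - sig(s - eps, t)) / (2 * eps) / rho
    return float(alpha), float(beta)


def buoyancy_frequency(
    upper: TSPoint, lower: TSPoint, dz: float
) -> StratificationSample:
    """Two-sensor buoyancy frequency squared and its T/S split.

    N^2 = (g / rho0) * (rho_lower - rho_upper) / dz from potential densities
    (positive = stable). The thermal part is ``g * alpha * dT/dz`` and the
    haline part ``-g * beta * dS/dz`` (z positive up), with alpha and beta
    evaluated at the mean T/S of the two sensors.
    """
    if dz <= 0:
        raise ValueError("dz must be > 0")
    if upper.pressure > lower.pressure:
        raise ValueError("upper sensor must be shallower than lower sensor")
    rho_u = potential_density(upper)
    rho_l = potential_density(lower)
    rho0 = 0.5 * (rho_u + rho_l)
    n2 = (G / rho0) * (rho_l - rho_u) / dz

    t_mean = 0.5 * (upper.temperature + lower.temperature)
    s_mean = 0.5 * (upper.salinity + lower.salinity)
    p_mean = 0.5 * (upper.pressure + lower.pressure)
    alpha, beta = expansion_contraction(s_mean, t_mean, p_mean)
    # z positive up: dT/dz = (T_upper - T_lower)/dz
    n2_t = G * alpha * (upper.temperature - lower.temperature) / dz
    n2_s = -G * beta * (upper.salinity - lower.salinity) / dz
    return StratificationSample(
        n2=n2, n2_t=n2_t, n2_s=n2_s, dz=dz, rho0=rho0, alpha=alpha, beta=beta
    )


# --------------------------------------------------------------------------
# Oxygen saturation and AOU
# --------------------------------------------------------------------------

_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7
_ML_PER_L_TO_UMOL_PER_L = 1000.0 / 22.3916  # ideal-gas molar volume of O2


def o2_saturation(point: TSPoint):
    """Oxygen saturation concentration (umol l-1) at atmospheric equilibrium.

    Garcia & Gordon (1992) fit to the Benson & Krause data, ml/l scale,
    converted to umol/l. Pressure dependence is not included (surface
    equilibration reference, the convention for AOU).
    """
    t = point.temperature
    s = point.salinity
    ts = np.log((298.15 - t) / (273.15 + t))
    a0, a1, a2, a3, a4, a5 = _GG_A
    b0, b1, b2, b3 = _GG_B
    ln_c = (
        a0
        + a1 * ts
        + a2 * ts**2
        + a3 * ts**3
        + a4 * ts**4
        + a5 * ts**5
        + s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
        + _GG_C0 * s**2
    )
    return float(np.exp(ln_c)) * _ML_PER_L_TO_UMOL_PER_L


def aou(o2_measured: float, point: TSPoint) -> float:
    """Apparent oxygen utilization (umol l-1).

    Saturation concentration at the sample's T/S minus the measured
    concentration; negative values indicate net photosynthetic oxygen
    production.
    """
    if o2_measured < 0:
        raise ValueError("measured oxygen must be >= 0")
    return o2_saturation(point) - o2_measured


def meltwater_fraction(
    s_obs: float,
    s_source: float | None = None,
    s_ice: float | None = None,
) -> float:
    """Volume fraction of sea-ice meltwater in observed surface water.

    Two-endmember salinity balance: the observed water is a mix of a source
    water (default Atlantic Water, S=35.1) and melted sea ice (bulk ice
    salinity default 8). Linear in ``s_obs``; 0 at the source salinity and
    1 at the ice salinity.
    """
    s_source = CONFIG["s_source"] if s_source is None else s_source
    s_ice = CONFIG["s_ice"] if s_ice is None else s_ice
    if s_source <= s_ice:
        raise ValueError("source salinity must exceed ice salinity")
    if not (s_ice <= s_obs <= s_source):
        raise ValueError("observed salinity outside endmember range")
    return (s_source - s_obs) / (s_source - s_ice)
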