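"""Carbonate system: alkalinity from salinity, DIC from pCO2, bloom takeup.

Total alkalinity is estimated from the regional linear salinity relation
``Alk = 736 + 45.2 * S`` (umol kg-1). DIC is then obtained by solving the
full carbonate equilibrium (carbonate, borate, water, phosphate, silicate
alkalinity terms) for the hydrogen-ion concentration at the measured pCO2.

Equilibrium constants (total hydrogen-ion pH scale, suitable for cold,
S = 30-35 waters) are declared in :data:`CONSTANTS_SET`:
K0 Weiss (1974); K1/K2 Lueker et al. (2000); KB Dickson (1990);
KW and phosphoric/silicic constants Millero (1995); boron/salinity ratio
Uppstrom (1974). The solver brackets pH in [3, 12] and is exact to the
tolerance of Brent's method; the pCO2 -> DIC -> pCO2 round trip closes to
well under 1 uatm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from moorbloom.seawater import density

CONSTANTS_SET = (
    "K0: Weiss 1974; K1,K2: Lueker et al. 2000 (total scale); "
    "KB: Dickson 1990; KW, KP1-3, KSi: Millero 1995; TB: Uppstrom 1974"
)

DEFAULT_PHOSPHATE = 0.5  # umol l-1
DEFAULT_SILICATE = 5.0  # umol l-1


@dataclass
class CarbonateState:
    """State of one carbonate-system computation (concentrations umol kg-1)."""

    pco2: float  # uatm
    alk: float  # umol kg-1
    temperature: float  # degC
    salinity: float  # practical
    phosphate: float = DEFAULT_PHOSPHATE  # umol l-1
    silicate: float = DEFAULT_SILICATE  # umol l-1
    dic: float | None = None  # umol kg-1, filled by the solver
    ph: float | None = None  # total scale, filled by the solver

    def __post_init__(self) -> None:
        if self.pco2 <= 0:
            raise ValueError("pCO2 must be positive")
        if self.alk <= 0:
            raise ValueError("alkalinity must be positive")


def alkalinity_from_salinity(s) -> float | np.ndarray:
    """Total alkalinity (umol kg-1) from the linear regional relation."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 42)):
        raise ValueError("salinity outside [0, 42]")
    out = 736.0 + 45.2 * s
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Equilibrium constants (mol/kg, total pH scale)
# ---------------------------------------------------------------------------

def _constants(t_c: float, s: float) -> dict[str, float]:
    t = t_c + 273.15
    lnt = np.log(t)
    sqs = np.sqrt(s)

    # CO2 solubility, mol kg-1 atm-1 (Weiss 1974)
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / t)
        + 23.3585 * np.log(t / 100.0)
        + s * (0.023517 - 0.023656 * (t / 100.0) + 0.0047036 * (t / 100.0) ** 2)
    )

    # Lueker et al. (2000), total scale
    pk1 = 3633.86 / t - 61.2172 + 9.6777 * lnt - 0.011555 * s + 0.0001152 * s**2
    pk2 = 471.78 / t + 25.9290 - 3.16967 * lnt - 0.01781 * s + 0.0001122 * s**2

    # Boric acid (Dickson 1990), total scale
    ln_kb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / t
        + 148.0248
        + 137.1942 * sqs
        + 1.62142 * s
        - (24.4344 + 25.085 * sqs + 0.2474 * s) * lnt
        + 0.053105 * sqs * t
    )

    # Water (Millero 1995)
    ln_kw = (
        148.9652
        - 13847.26 / t
        - 23.6521 * lnt
        + (118.67 / t - 5.977 + 1.0495 * lnt) * sqs
        - 0.01615 * s
    )

    # Phosphoric acid (Millero 1995)
    ln_kp1 = (
        -4576.752 / t
        + 115.525
        - 18.453 * lnt
        + (-106.736 / t + 0.69171) * sqs
        + (-0.65643 / t - 0.01844) * s
    )
    ln_kp2 = (
        -8814.715 / t
        + 172.0883
        - 27.927 * lnt
        + (-160.340 / t + 1.3566) * sqs
        + (0.37335 / t - 0.05778) * s
    )
    ln_kp3 = (
        -3070.75 / t
        - 18.141
        + (17.27039 / t + 2.81197) * sqs
        + (-44.99486 / t - 0.09984) * s
    )

    # Silicic acid (Millero 1995), ionic strength form
    ii = 19.924 * s / (1000.0 - 1.005 * s)
    ln_ksi = (
        -8904.2 / t
        + 117.385
        - 19.334 * lnt
        + (-458.79 / t + 3.5913) * np.sqrt(ii)
        + (188.74 / t - 1.5998) * ii
        + (-12.1652 / t + 0.07871) * ii**2
        + np.log(1.0 - 0.001005 * s)
    )

    return {
        "k0": float(np.exp(ln_k0)),
        "k1": float(10.0**-pk1),
        "k2": float(10.0**-pk2),
        "kb": float(np.exp(ln_kb)),
        "kw": float(np.exp(ln_kw)),
        "kp1": float(np.exp(ln_kp1)),
        "kp2": float(np.exp(ln_kp2)),
        "kp3": float(np.exp(ln_kp3)),
        "ksi": float(np.exp(ln_ksi)),
        "tb": 0.000416 * s / 35.0,  # total boron, mol/kg (Uppstrom 1974)
    }


def _minor_alkalinity(h: float, k: dict[str, float], tp: float, tsi: float) -> float:
    """Non-carbonate alkalinity terms (mol/kg) at [H+] = h."""
    boh4 = k["tb"] * k["kb"] / (k["kb"] + h)
    oh = k["kw"] / h
    d = h**3 + k["kp1"] * h**2 + k["kp1"] * k["kp2"] * h + k["kp1"] * k["kp2"] * k["kp3"]
    h3po4 = tp * h**3 / d
    hpo4 = tp * k["kp1"] * k["kp2"] * h / d
    po4 = tp * k["kp1"] * k["kp2"] * k["kp3"] / d
    sioh3 = tsi * k["ksi"] / (k["ksi"] + h)
    return boh4 + oh + hpo4 + 2.0 * po4 - h3po4 + sioh3 - h


def _umol_l_to_mol_kg(c_umol_l: float, t_c: float, s: float) -> float:
    rho = density(s, t_c, 0.0)  # kg m-3
    return c_umol_l * 1e-6 / (rho / 1000.0)


def dic_from_pco2(state: CarbonateState) -> CarbonateState:
    """Solve the carbonate system for DIC (umol kg-1) at given pCO2 and Alk.

    Dissolved CO2 is fixed by ``[CO2*] = K0 * pCO2``; the hydrogen-ion
    concentration is found so total alkalinity balances, then
    ``DIC = [CO2*] * (1 + K1/h + K1*K2/h^2)``. DIC increases monotonically
    with pCO2 at fixed Alk/T/S. Returns a copy of the state with ``dic``
    and ``ph`` filled.
    """
    k = _constants(state.temperature, state.salinity)
    co2 = k["k0"] * state.pco2 * 1e-6  # mol/kg
    ta = state.alk * 1e-6
    tp = _umol_l_to_mol_kg(state.phosphate, state.temperature, state.salinity)
    tsi = _umol_l_to_mol_kg(state.silicate, state.temperature, state.salinity)

    def residual(ph: float) -> float:
        h = 10.0**-ph
        carb = co2 * (k["k1"] / h + 2.0 * k["k1"] * k["k2"] / h**2)
        return carb + _minor_alkalinity(h, k, tp, tsi) - ta

    try:
        ph = brentq(residual, 3.0, 12.0, xtol=1e-12, rtol=8.9e-16)
    except ValueError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(
            f"carbonate solver did not converge (pCO2={state.pco2}, "
            f"Alk={state.alk}, T={state.temperature}, S={state.salinity})"
        ) from exc
    h = 10.0**-ph
    dic = co2 * (1.0 + k["k1"] / h + k["k1"] * k["k2"] / h**2)
    return dc_replace(state, dic=dic * 1e6, ph=ph)


def pco2_from_dic(
    dic: float,
    alk: float,
    temperature: float,
    salinity: float,
    phosphate: float = DEFAULT_PHOSPHATE,
    silicate: float = DEFAULT_SILICATE,
) -> float:
    """pCO2 (uatm) from DIC and alkalinity (both umol kg-1); inverse route."""
    k = _constants(temperature, salinity)
    dic_m = dic * 1e-6
    ta = alk * 1e-6
    tp = _umol_l_to_mol_kg(phosphate, temperature, salinity)
    tsi = _umol_l_to_mol_kg(silicate, temperature, salinity)

    def residual(ph: float) -> float:
        h = 10.0**-ph
        gamma = h**2 + k["k1"] * h + k["k1"] * k["k2"]
        carb = dic_m * (k["k1"] * h + 2.0 * k["k1"] * k["k2"]) / gamma
        return carb + _minor_alkalinity(h, k, tp, tsi) - ta

    ph = brentq(residual, 3.0, 12.0, xtol=1e-12, rtol=8.9e-16)
    h = 10.0**-ph
    co2 = dic_m * h**2 / (h**2 + k["k1"] * h + k["k1"] * k["k2"])
    return co2 / k["k0"] * 1e6


def carbon_takeup(
    pco2: pd.Series,
    salinity: pd.Series,
    temperature: pd.Series,
    bloom_start,
    phosphate: float = DEFAULT_PHOSPHATE,
    silicate: float = DEFAULT_SILICATE,
) -> float:
    """Bloom DIC drawdown (umol kg-1) from a pCO2 record.

    The carbon takeup is the DIC change between the beginning of the bloom
    and the time the pCO2 minimum is reached, with alkalinity from salinity
    at each endpoint. Positive for a drawdown.
    """
    bloom_start = pd.Timestamp(bloom_start)
    if not (pco2.index[0] <= bloom_start <= pco2.index[-1]):
        raise ValueError("bloom_start outside the pCO2 record")
    after = pco2.loc[bloom_start:].dropna()
    if after.empty:
        raise ValueError("no pCO2 data after bloom start")
    t_min = after.idxmin()

    def state_at(ts) -> CarbonateState:
        # nearest-sample lookup keeps the routine tolerant of small gaps
        i = pco2.index.get_indexer([ts], method="nearest")[0]
        s = float(salinity.iloc[salinity.index.get_indexer([ts], method="nearest")[0]])
        t = float(
            temperature.iloc[temperature.index.get_indexer([ts], method="nearest")[0]]
        )
        return CarbonateState(
            pco2=float(pco2.iloc[i]),
            alk=float(alkalinity_from_salinity(s)),
            temperature=t,
            salinity=s,
            phosphate=phosphate,
            silicate=silicate,
        )

    dic_start = dic_from_pco2(state_at(bloom_start)).dic
    dic_min = dic_from_pco2(state_at(t_min)).dic
    return float(dic_start - dic_min)


def apply_pco2_bias(
    series: pd.Series, offset: float, window: tuple | None = None
) -> pd.Series:
    """Subtract a constant pCO2 bias (uatm) over one deployment window.

    Sensor records occasionally carry a constant high bias (a step jump at
    a mooring turn-around); the correction subtracts ``offset`` inside
    ``window = (start, end)`` (whole record if None) and leaves all other
    samples untouched.
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    out = series.copy()
    if window is None:
        out -= offset
    else:
        start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
        sel = (out.index >= start) & (out.index <= end)
        out[sel] = out[sel] - offset
    return out
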