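"""Sediment-trap flux normalizations, benthic O2-to-POC conversion, and
acoustic-backscatter normalization.

Water-column traps record the height of sediment in 4-cm cups, normalized
by the 0.5 m2 collection area and cup-opening duration; the bottom-lander
trap records POC mass normalized by split factor, 0.25 m2 area and
duration. Benthic oxygen consumption converts to a POC flux at a
respiratory quotient of 1. ADCP mean volume backscattering strength (MVBS)
is layer-averaged and normalized by the per-deployment median to remove
hardware offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CARBON_MOLAR_MASS = 12.011
CUP_RADIUS_CM = 2.0  # interior diameter 4 cm
TRAP_AREA_M2 = 0.5
LANDER_AREA_M2 = 0.25
MVBS_LAYER = (50.0, 100.0)  # m


@dataclass
class TrapRecord:
    """One sediment-trap cup interval."""

    open: pd.Timestamp
    close: pd.Timestamp
    sediment_height_cm: float | None = None  # water-column cups
    poc_mass_mg: float | None = None  # lander trap
    split_factor: float = 1.0
    collection_area_m2: float | None = None

    def __post_init__(self) -> None:
        self.open = pd.Timestamp(self.open)
        self.close = pd.Timestamp(self.close)
        if not self.open < self.close:
            raise ValueError("cup open date must precede close date")
        if self.split_factor <= 0:
            raise ValueError("split factor must be positive")

    @property
    def duration_days(self) -> float:
        return (self.close - self.open) / pd.Timedelta(days=1)


def sediment_volume_flux(record: TrapRecord) -> float:
    """Sediment volume flux (ml m-2 day-1) from cup sediment height.

    Cylinder volume pi * r^2 * height (r = 2 cm) normalized by the 0.5 m2
    collection area and the opening duration.
    """
    if record.sediment_height_cm is None or record.sediment_height_cm < 0:
        raise ValueError("sediment height (cm) required and >= 0")
    area = record.collection_area_m2 or TRAP_AREA_M2
    volume_ml = math.pi * CUP_RADIUS_CM**2 * record.sediment_height_cm  # cm3 = ml
    return volume_ml / (area * record.duration_days)


def lander_poc_flux(record: TrapRecord) -> float:
    """POC flux (mg C m-2 day-1) from the bottom-lander trap.

    Measured POC mass divided by split factor, the 0.25 m2 collection area
    and the opening duration.
    """
    if record.poc_mass_mg is None or record.poc_mass_mg < 0:
        raise ValueError("POC mass (mg) required and >= 0")
    area = record.collection_area_m2 or LANDER_AREA_M2
    return record.poc_mass_mg / record.split_factor / area / record.duration_days


def benthic_o2_to_poc(o2_flux_mmol_m2_day: float, rq: float = 1.0) -> float:
    """POC flux (mg C m-2 day-1) from benthic O2 consumption.

    At a respiratory quotient RQ, each mmol of O2 consumed mineralizes
    RQ mmol of organic carbon: flux * RQ * 12.011 mg/mmol.
    """
    if o2_flux_mmol_m2_day < 0:
        raise ValueError("oxygen flux must be >= 0")
    return o2_flux_mmol_m2_day * rq * CARBON_MOLAR_MASS


def detritus_coverage(counts: dict[str, int], n_boxes: int = 100) -> dict[str, float]:
    """Seafloor coverage (%) per detritus class from image-box tallies.

    Frame grabs are divided into ``n_boxes`` equal-area boxes; each box is
    tallied as bare, white (aged fine material) or green (fresh algal
    detritus). Counts must not exceed the number of boxes.
    """
    total = sum(counts.values())
    if total > n_boxes:
        raise ValueError(f"counts sum to {total} > {n_boxes} boxes")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be >= 0")
    return {cls: 100.0 * c / n_boxes for cls, c in counts.items()}


def normalized_mvbs(
    mvbs: pd.DataFrame,
    deployments: list[tuple] | None = None,
    layer: tuple[float, float] = MVBS_LAYER,
    db_average: bool = True,
) -> pd.Series:
    """Daily layer-mean MVBS anomaly (dB) relative to the deployment median.

    ``mvbs`` is time x depth (columns are bin depths in m). The vertical
    mean over ``layer`` is taken directly in dB by default (set
    ``db_average=False`` for linear-power averaging), averaged to daily
    values; the median of those daily values within each deployment window
    is subtracted, removing hardware offsets between deployments.
    """
    depths = np.asarray(mvbs.columns, dtype=float)
    sel = (depths >= layer[0]) & (depths <= layer[1])
    if not sel.any():
        raise ValueError("no depth bins inside the averaging layer")
    sub = mvbs.loc[:, mvbs.columns[sel]]
    if db_average:
        vmean = sub.mean(axis=1)
    else:
        vmean = 10.0 * np.log10((10.0 ** (sub / 10.0)).mean(axis=1))
    daily = vmean.groupby(vmean.index.floor("D")).mean()

    if deployments is None:
        deployments = [(daily.index[0], daily.index[-1])]
    out = daily.copy()
    for d0, d1 in deployments:
        win = (out.index >= pd.Timestamp(d0)) & (out.index <= pd.Timestamp(d1))
        out[win] = daily[win] - daily[win].median()
    out.name = "mvbs_anomaly_db"
    return out


def mvbs_from_counts(
    counts, noise_floor_counts: float, conversion_db_per_count: float = 0.45,
    offset_db: float = 0.0,
):
    """Thin sonar-equation operator: echo-intensity counts to relative dB.

    ``10*log10(10^(kc*E/10) - 10^(kc*E_noise/10)) + offset`` with
    user-supplied calibration ``kc`` (dB/count) and offset; constants are
    instrument-specific and must come from calibration, so no defaults
    beyond the generic count slope are claimed.
    """
    counts = np.asarray(counts, dtype=float)
    lin = 10.0 ** (conversion_db_per_count * counts / 10.0)
    lin_noise = 10.0 ** (conversion_db_per_count * noise_floor_counts / 10.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 10.0 * np.log10(np.maximum(lin - lin_noise, np.nan)) + offset_db
    return out
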