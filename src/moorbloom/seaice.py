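"""Gridded sea-ice concentration metrics and gate area export.

Percent-of-days ice cover, signed great-circle distance from a point to
the 20 % ice-concentration edge (negative inside the ice), and the ice
area exported across a gate as the integral of drift normal to the gate
times ice concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
ICE_EDGE_THRESHOLD = 20.0  # percent concentration


@dataclass
class GriddedIceField:
    """Daily ice concentration (and optional drift) on a lat/lon grid.

    ``conc`` has shape (n_days, nlat, nlon) in percent; drift components
    ``u`` (eastward) and ``v`` (northward) are km/day on the same grid.
    """

    time: pd.DatetimeIndex
    lat: np.ndarray  # (nlat,)
    lon: np.ndarray  # (nlon,)
    conc: np.ndarray  # (n_days, nlat, nlon), percent
    u: np.ndarray | None = None
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        expected = (len(self.time), len(self.lat), len(self.lon))
        if self.conc.shape != expected:
            raise ValueError(f"conc shape {self.conc.shape} != {expected}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.conc) < 0 or np.nanmax(self.conc) > 100:
                raise ValueError("concentration must lie in [0, 100] percent")
        for name in ("u", "v"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=float)
                if arr.shape != expected:
                    raise ValueError(f"{name} shape {arr.shape} != {expected}")
                setattr(self, name, arr)

    def day_slice(self, when) -> np.ndarray:
        i = self.time.get_indexer([pd.Timestamp(when)])[0]
        if i < 0:
            raise KeyError(f"day {when} not in field")
        return self.conc[i]


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance (km) on a spherical Earth."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pct_ice_days(
    field: GriddedIceField, months=None, threshold: float = ICE_EDGE_THRESHOLD
) -> np.ndarray:
    """Percent of days with ice concentration strictly above threshold.

    ``months`` optionally restricts to a month selection (e.g. (4, 5, 6)
    for April-June). Per cell: 100 * #days(conc > threshold) / #days with
    data; cells with no data are NaN.
    """
    conc = field.conc
    if months is not None:
        sel = field.time.month.isin(tuple(months))
        conc = conc[np.asarray(sel)]
    with_data = np.isfinite(conc)
    n_data = with_data.sum(axis=0).astype(float)
    n_icy = ((conc > threshold) & with_data).sum(axis=0)
    out = np.full(n_data.shape, np.nan)
    has = n_data > 0
    out[has] = 100.0 * n_icy[has] / n_data[has]
    return out


def distance_to_edge(
    field: GriddedIceField,
    when,
    point_lat: float,
    point_lon: float,
    threshold: float = ICE_EDGE_THRESHOLD,
) -> float:
    """Signed distance (km) from a point to the ice edge on one day.

    If the concentration at the point's cell is below the threshold (open
    water) the distance to the nearest cell exceeding the threshold is
    returned as positive; if the point sits in ice (> threshold), the
    distance to the nearest below-threshold cell is returned as negative.
    A uniform field has no edge: NaN with a warning.
    """
    conc = field.day_slice(when)
    lat2d, lon2d = np.meshgrid(field.lat, field.lon, indexing="ij")
    i = int(np.argmin(np.abs(field.lat - point_lat)))
    j = int(np.argmin(np.abs(field.lon - point_lon)))
    at_point = conc[i, j]
    if not np.isfinite(at_point):
        return float("nan")
    in_ice = at_point > threshold
    target = (conc <= threshold) if in_ice else (conc > threshold)
    target &= np.isfinite(conc)
    if not target.any():
        warnings.warn("distance_to_edge: uniform field, no opposite class", stacklevel=2)
        return float("nan")
    dists = great_circle_km(point_lat, point_lon, lat2d[target], lon2d[target])
    d = float(dists.min())
    return -d if in_ice else d


@dataclass
class Gate:
    """Polyline gate for area-export integrals.

    ``vertices`` is a list of (lat, lon); ``positive_normal`` gives the
    export-positive side as a compass direction, one of
    {"north", "south", "east", "west"} applied to every segment.
    """

    vertices: list[tuple[float, float]]
    positive_normal: str = "south"

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("gate needs at least two vertices")
        if self.positive_normal not in ("north", "south", "east", "west"):
            raise ValueError("positive_normal must be a compass direction")


def _segment_samples(gate: Gate, samples_per_segment: int):
    """Sample points and per-sample lengths (km) along the gate polyline."""
    pts, lens = [], []
    for (la1, lo1), (la2, lo2) in zip(gate.vertices, gate.vertices[1:]):
        seg_len = great_circle_km(la1, lo1, la2, lo2)
        frac = (np.arange(samples_per_segment) + 0.5) / samples_per_segment
        pts.append(np.column_stack([la1 + frac * (la2 - la1), lo1 + frac * (lo2 - lo1)]))
        lens.append(np.full(samples_per_segment, seg_len / samples_per_segment))
    return np.concatenate(pts), np.concatenate(lens)


def area_export(
    field: GriddedIceField,
    gate: Gate,
    samples_per_segment: int = 50,
) -> pd.Series:
    """Daily ice area export (km2/day) across a gate.

    For each day the flux is the sum over gate samples of (drift component
    along the positive normal) x (ice concentration fraction) x (sample
    length). Nearest-cell drift and concentration are used at each sample;
    samples over cells with missing drift are skipped.
    """
    if field.u is None or field.v is None:
        raise ValueError("area_export requires drift components u and v")
    pts, lens = _segment_samples(gate, samples_per_segment)
    lat_idx = np.argmin(np.abs(field.lat[None, :] - pts[:, 0:1]), axis=1)
    lon_idx = np.argmin(np.abs(field.lon[None, :] - pts[:, 1:2]), axis=1)

    sign = {"north": ("v", 1.0), "south": ("v", -1.0),
            "east": ("u", 1.0), "west": ("u", -1.0)}[gate.positive_normal]
    comp = field.u if sign[0] == "u" else field.v

    out = np.zeros(len(field.time))
    for d in range(len(field.time)):
        drift = comp[d, lat_idx, lon_idx] * sign[1]  # km/day toward positive side
        conc_frac = field.conc[d, lat_idx, lon_idx] / 100.0
        ok = np.isfinite(drift) & np.isfinite(conc_frac)
        out[d] = float(np.sum(drift[ok] * conc_frac[ok] * lens[ok]))
    return pd.Series(out, index=field.time, name="ice_area_export_km2_per_day")
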