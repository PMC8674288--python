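"""Moored sensor time-series container and conditioning operations.

The :class:`MooringSeries` is the package's in-memory currency: one physical
variable at one nominal instrument depth, with UTC timestamps, declared
units and per-sample QC flags.  Conditioning covers burst averaging,
blow-down masking (instruments dragged down by strong currents), zero-phase
low-pass filtering and daily aggregation.  Masked samples never enter any
downstream average.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal


class QCFlag(enum.IntEnum):
    """Per-sample quality flag. Any non-OK flag excludes the sample."""

    OK = 0
    BELOW_DETECTION = 1  # value floored at a detection limit (still usable)
    BLOWDOWN = 2
    MISSING = 3

    @classmethod
    def bad(cls) -> tuple["QCFlag", ...]:
        return (cls.BLOWDOWN, cls.MISSING)


@dataclass
class MooringSeries:
    """One variable at one nominal depth on a mooring.

    Parameters
    ----------
    time
        UTC timestamps, strictly increasing.
    values
        Physical values in ``units``; NaN means missing.
    units
        Unit string, non-empty (e.g. ``"umol l-1"``).
    name
        Variable name (e.g. ``"nitrate"``).
    nominal_depth
        Design depth of the instrument, metres positive down.
    actual_depth
        Instantaneous instrument depth from pressure, if recorded.
    qc
        Per-sample :class:`QCFlag` values; defaults to OK (MISSING where
        the value is NaN).
    """

    time: pd.DatetimeIndex
    values: np.ndarray
    units: str
    name: str = "variable"
    nominal_depth: float | None = None
    actual_depth: np.ndarray | None = None
    qc: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = pd.DatetimeIndex(self.time)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.time) != len(self.values):
            raise ValueError("time and values length mismatch")
        if not self.units:
            raise ValueError("units must be declared and non-empty")
        if len(self.time) > 1 and not self.time.is_monotonic_increasing:
            raise ValueError("time must be strictly increasing")
        if len(self.time) > 1 and self.time.has_duplicates:
            raise ValueError("time must be strictly increasing (duplicates)")
        if self.actual_depth is not None:
            self.actual_depth = np.asarray(self.actual_depth, dtype=float)
            if len(self.actual_depth) != len(self.values):
                raise ValueError("actual_depth length mismatch")
        if self.qc is None:
            self.qc = np.where(np.isnan(self.values), QCFlag.MISSING, QCFlag.OK)
        self.qc = np.asarray(self.qc, dtype=np.int8)
        if len(self.qc) != len(self.values):
            raise ValueError("qc length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of samples usable downstream."""
        bad = np.isin(self.qc, QCFlag.bad())
        return ~bad & ~np.isnan(self.values)

    def masked_values(self) -> np.ndarray:
        """Values with non-usable samples replaced by NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.masked_values(), index=self.time, name=self.name)

    def with_values(self, values: np.ndarray, **kw) -> "MooringSeries":
        return replace(self, values=np.asarray(values, dtype=float), **kw)


@dataclass
class Deployment:
    """One mooring deployment window with its instrument depths."""

    site_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    instrument_depths: list[float]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if not self.start < self.end:
            raise ValueError("deployment start must precede end")
        depths = list(self.instrument_depths)
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("instrument depths must be strictly increasing")


# ---------------------------------------------------------------------------
# Conditioning operations
# ---------------------------------------------------------------------------

def burst_average(samples: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Linear average of one burst of ~1 s samples to a single hourly value.

    Instruments record k samples (k in {5, 8, 10}) one second apart per hour;
    the hourly value is the arithmetic mean of the unmasked ones. An empty
    (or fully masked) burst yields NaN.
    """
    x = np.asarray(samples, dtype=float)
    if mask is not None:
        x = x[~np.asarray(mask, dtype=bool)]
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan")
    return float(x.mean())


def burst_series_to_hourly(
    time: pd.DatetimeIndex, values: np.ndarray, **series_kw
) -> MooringSeries:
    """Collapse burst-resolved samples to hourly means stamped at burst start.

    Samples are grouped by the hour they fall in (bursts last a few seconds,
    so a burst never straddles an hour boundary in practice).
    """
    s = pd.Series(np.asarray(values, dtype=float), index=pd.DatetimeIndex(time))
    hourly = s.groupby(s.index.floor("h")).mean()
    return MooringSeries(time=hourly.index, values=hourly.to_numpy(), **series_kw)


def mask_blowdowns(series: MooringSeries, threshold_m: float = 10.0) -> MooringSeries:
    """Flag samples where the instrument was dragged deeper than nominal.

    Strong currents intermittently push moored instruments down (excursions
    up to ~200 m); such samples traverse vertical property gradients and are
    excluded. A sample is flagged BLOWDOWN when
    ``actual_depth - nominal_depth > threshold_m``; other flags are kept.
    Without recorded actual depth this is a no-op with a warning.
    """
    if series.actual_depth is None or series.nominal_depth is None:
        warnings.warn(
            "mask_blowdowns: no actual_depth/nominal_depth; series unchanged",
            stacklevel=2,
        )
        return series
    excursion = series.actual_depth - series.nominal_depth
    qc = series.qc.copy()
    hit = (excursion > threshold_m) & (qc == QCFlag.OK)
    qc[hit] = QCFlag.BLOWDOWN
    return replace(series, qc=qc)


def _interpolate_short_gaps(s: pd.Series, max_gap_hours: int) -> pd.Series:
    return s.interpolate(method="time", limit=max_gap_hours, limit_area="inside")


def lowpass(
    series: MooringSeries,
    cutoff_days: float = 5.0,
    max_gap_hours: int = 6,
    order: int = 4,
) -> MooringSeries:
    """Zero-phase low-pass filter of an hourly series.

    A Butterworth filter of the given order is applied forward-backward
    (``filtfilt``) so the output is phase-free, with the half-power point at
    ``1 / cutoff_days`` cycles per day. Gaps up to ``max_gap_hours`` are
    linearly interpolated first; longer gaps propagate as missing over their
    extent. The DC component (record mean) is preserved.
    """
    s = series.to_pandas()
    if len(s) < 2:
        raise ValueError("series too short to filter")
    step = s.index.to_series().diff().dropna()
    if not (step == pd.Timedelta(hours=1)).all():
        raise ValueError("lowpass expects regular hourly spacing")
    cutoff_per_hour = 1.0 / (cutoff_days * 24.0)  # cycles per sample
    nyquist = 0.5
    wn = cutoff_per_hour / nyquist
    b, a = signal.butter(order, wn, btype="low")
    # filtfilt default padlen; require a comfortably longer record
    min_len = 3 * (3 * max(len(a), len(b)))
    if len(s) < max(min_len, 3 * int(cutoff_days * 24)):
        raise ValueError("series shorter than 3x the filter length")

    filled = _interpolate_short_gaps(s, max_gap_hours)
    out = np.full(len(filled), np.nan)
    vals = filled.to_numpy()
    # filter each contiguous valid segment independently (reflective padding
    # inside filtfilt handles the edges)
    isfin = np.isfinite(vals)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], isfin.view(np.int8), [0]))))
    for start, stop in idx.reshape(-1, 2):
        seg = vals[start:stop]
        if len(seg) >= max(3 * order + 1, 24):
            out[start:stop] = signal.filtfilt(b, a, seg)
        # very short segments stay missing
    qc = np.where(np.isnan(out), QCFlag.MISSING, QCFlag.OK).astype(np.int8)
    return replace(series, values=out, qc=qc, actual_depth=None)


def daily_mean(series: MooringSeries, min_samples: int = 6) -> MooringSeries:
    """Calendar-day (UTC) mean of an hourly series.

    Days with fewer than ``min_samples`` valid hourly values are reported
    missing rather than biased by partial coverage.
    """
    s = series.to_pandas()
    grouped = s.groupby(s.index.floor("D"))
    mean = grouped.mean()
    count = grouped.count()
    vals = mean.to_numpy()
    vals[count.to_numpy() < min_samples] = np.nan
    return MooringSeries(
        time=mean.index,
        values=vals,
        units=series.units,
        name=series.name,
        nominal_depth=series.nominal_depth,
        meta=dict(series.meta),
    )


# ---------------------------------------------------------------------------
# I/O: CSV (ISO-8601 time column) and CF-style NetCDF
# ---------------------------------------------------------------------------

def to_csv(series: MooringSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time": series.time.strftime("%Y-%m-%dT%H:%M:%S"),
            "value": series.values,
            "qc_flag": series.qc,
        }
    )
    if series.actual_depth is not None:
        df["actual_depth"] = series.actual_depth
    with open(path, "w") as fh:
        fh.write(f"# name: {series.name}\n")
        fh.write(f"# units: {series.units}\n")
        if series.nominal_depth is not None:
            fh.write(f"# nominal_depth: {series.nominal_depth}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # bit-exact round trip


def from_csv(path) -> MooringSeries:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    return MooringSeries(
        time=pd.DatetimeIndex(pd.to_datetime(df["time"])),
        values=df["value"].to_numpy(),
        qc=df["qc_flag"].to_numpy(),
        actual_depth=df["actual_depth"].to_numpy() if "actual_depth" in df else None,
        units=header.get("units", ""),
        name=header.get("name", "variable"),
        nominal_depth=float(header["nominal_depth"]) if "nominal_depth" in header else None,
    )


def to_netcdf(series: MooringSeries, path) -> None:
    """Write a CF-style NetCDF3 file (time coordinate, units attributes)."""
    import xarray as xr

    ds = xr.Dataset(
        {
            series.name: ("time", series.values, {"units": series.units}),
            "qc_flag": ("time", series.qc.astype(np.int32)),
        },
        coords={"time": series.time},
    )
    if series.actual_depth is not None:
        ds["actual_depth"] = ("time", series.actual_depth, {"units": "m"})
    if series.nominal_depth is not None:
        ds.attrs["nominal_depth_m"] = float(series.nominal_depth)
    ds.attrs["variable"] = series.name
    ds.to_netcdf(path, engine="scipy")


def from_netcdf(path) -> MooringSeries:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy", decode_timedelta=False) as ds:
        name = ds.attrs.get("variable")
        if name is None:
            name = [v for v in ds.data_vars if v not in ("qc_flag", "actual_depth")][0]
        var = ds[name]
        return MooringSeries(
            time=pd.DatetimeIndex(ds["time"].values),
            values=np.asarray(var.values, dtype=float),
            qc=np.asarray(ds["qc_flag"].values) if "qc_flag" in ds else None,
            actual_depth=(
                np.asarray(ds["actual_depth"].values, dtype=float)
                if "actual_depth" in ds
                else None
            ),
            units=var.attrs.get("units", ""),
            name=str(name),
            nominal_depth=ds.attrs.get("nominal_depth_m"),
        )
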