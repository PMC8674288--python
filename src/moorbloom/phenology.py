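"""Bloom phenology, stoichiometric regressions, and regime classification.

Bloom onset is when the net surface heat flux turns (and stays) positive so
deep winter mixing stops and stratification can set in; bloom end is
nitrate depletion in the productive layer (absent in the meltwater regime,
where the bloom fades rather than crashes). The early-bloom coupling
between nitrate, oxygen (AOU), pCO2 and chlorophyll is summarized by
ordinary least-squares slopes of daily averages, and the stratification
regime of a (MLD, dS) state is classified as meltwater (MW), mixed-layer
(ML) or unstratified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_MONTH = 30.44  # mean month length used for durations and lags

REGIME_MW = "MW"
REGIME_ML = "ML"
REGIME_UNSTRATIFIED = "unstratified"


@dataclass
class RegimeParams:
    """Thresholds of the stratification-regime classification."""

    mld_threshold: float = 50.0  # m
    ds_threshold: float = 1.0  # salinity difference, surface minus 100 m

    def __post_init__(self) -> None:
        if self.mld_threshold <= 0 or self.ds_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RegressionFit:
    """y = m*x + b ordinary least-squares fit with r^2 and sample size."""

    m: float
    b: float
    r2: float
    n: int


@dataclass
class BloomSummary:
    """Per-regime derived phenology and budget summary."""

    regime: str
    bloom_start: pd.Timestamp | None = None
    bloom_end: pd.Timestamp | None = None
    growth_rate: float | None = None  # day-1 e-folding
    slopes: dict = field(default_factory=dict)
    export_peak_dates: dict = field(default_factory=dict)
    export_lags_months: dict = field(default_factory=dict)
    retention_months: float | None = None

    @property
    def duration_months(self) -> float | None:
        if self.bloom_start is None or self.bloom_end is None:
            return None
        return (self.bloom_end - self.bloom_start) / pd.Timedelta(days=DAYS_PER_MONTH)


# ---------------------------------------------------------------------------
# Onset / end / growth
# ---------------------------------------------------------------------------

def detect_bloom_onset(heat_flux: pd.Series, persistence_days: int = 5) -> pd.Timestamp:
    """First date from which daily net surface heat flux stays positive.

    Positive flux warms the ocean; once it stays positive for at least
    ``persistence_days`` consecutive days, winter deep mixing stops,
    stratification sets in, and the bloom can start. Raises if no such
    date exists.
    """
    hf = heat_flux.dropna()
    if hf.empty:
        raise ValueError("empty heat-flux series")
    positive = (hf.to_numpy() > 0).astype(int)
    run = 0
    for i, p in enumerate(positive):
        run = run + 1 if p else 0
        if run >= persistence_days:
            start_i = i - persistence_days + 1
            # extend back through the uninterrupted positive run
            while start_i > 0 and positive[start_i - 1]:
                start_i -= 1
            return pd.Timestamp(hf.index[start_i])
    raise ValueError("heat flux never stays positive for the persistence window")


def detect_bloom_end(
    nitrate: pd.Series,
    onset=None,
    depletion_threshold: float = 1.0,
) -> pd.Timestamp | None:
    """First post-onset date with productive-layer nitrate below threshold.

    Returns None (missing) for non-crashing blooms that never deplete
    nitrate, as in the meltwater regime.
    """
    ni = nitrate.dropna()
    if onset is not None:
        ni = ni.loc[pd.Timestamp(onset):]
    below = ni[ni < depletion_threshold]
    if below.empty:
        return None
    return pd.Timestamp(below.index[0])


def efolding_growth_rate(chl: pd.Series, window: tuple | None = None) -> float:
    """E-folding growth rate (day-1) from a log-linear chlorophyll fit.

    Least-squares slope of ln(chl) against time over the window. Requires
    at least 5 positive values; non-positive values are excluded with a
    warning (they carry no exponential-phase information).
    """
    s = chl.dropna()
    if window is not None:
        s = s.loc[pd.Timestamp(window[0]): pd.Timestamp(window[1])]
    pos = s[s > 0]
    if len(pos) < len(s):
        warnings.warn(
            f"efolding_growth_rate: excluded {len(s) - len(pos)} non-positive values",
            stacklevel=2,
        )
    if len(pos) < 5:
        raise ValueError("need at least 5 positive chlorophyll values")
    t_days = (pos.index - pos.index[0]) / pd.Timedelta(days=1)
    fit = stats.linregress(np.asarray(t_days, dtype=float), np.log(pos.to_numpy()))
    return float(fit.slope)


# ---------------------------------------------------------------------------
# Stoichiometric regressions (daily averages over the bloom window)
# ---------------------------------------------------------------------------

STOICH_PAIRS = (
    ("nitrate", "aou"),
    ("pco2", "aou"),
    ("chl", "aou"),
    ("nitrate", "chl"),
)


def regress_pair(x: pd.Series, y: pd.Series, min_pairs: int = 10) -> RegressionFit:
    """OLS y = m*x + b on paired daily values (r^2 via Pearson)."""
    df = pd.concat({"x": x, "y": y}, axis=1).dropna()
    if len(df) < min_pairs:
        raise ValueError(f"only {len(df)} paired values; need >= {min_pairs}")
    fit = stats.linregress(df["x"].to_numpy(), df["y"].to_numpy())
    return RegressionFit(m=float(fit.slope), b=float(fit.intercept),
                         r2=float(fit.rvalue) ** 2, n=len(df))


def stoichiometry_regressions(
    daily: pd.DataFrame,
    bloom_window: tuple,
    post_window: tuple | None = None,
    pairs=STOICH_PAIRS,
    min_pairs: int = 10,
) -> dict[str, dict[str, RegressionFit]]:
    """Least-squares slopes of the bloom's elemental coupling.

    ``daily`` holds daily averages in columns (nitrate, aou, pco2, chl).
    For each (x, y) pair the OLS fit over ``bloom_window`` is returned
    under key ``"y_vs_x"``, and optionally a second fit over the
    post-bloom window under ``"post"``.
    """
    out: dict[str, dict[str, RegressionFit]] = {}
    windows = {"bloom": bloom_window}
    if post_window is not None:
        windows["post"] = post_window
    for x_name, y_name in pairs:
        key = f"{y_name}_vs_{x_name}"
        out[key] = {}
        for wname, (w0, w1) in windows.items():
            sel = daily.loc[pd.Timestamp(w0): pd.Timestamp(w1)]
            out[key][wname] = regress_pair(sel[x_name], sel[y_name], min_pairs)
    return out


# ---------------------------------------------------------------------------
# Regime classification and areal coverage
# ---------------------------------------------------------------------------

def classify_regime(mld: float, ds: float, params: RegimeParams | None = None) -> str:
    """Classify one (MLD, dS) state.

    MW when MLD < 50 m and dS > 1 (strong meltwater halocline); ML when
    MLD < 50 m and dS < 1; otherwise unstratified. Equality at the dS
    boundary goes to ML; MLD at the threshold counts as unstratified.
    """
    p = params or RegimeParams()
    if not (np.isfinite(mld) and np.isfinite(ds)):
        raise ValueError("mld and ds must be finite")
    if mld < p.mld_threshold:
        return REGIME_MW if ds > p.ds_threshold else REGIME_ML
    return REGIME_UNSTRATIFIED


def regime_area(
    mld_grid, ds_grid, cell_areas, params: RegimeParams | None = None
) -> dict[str, float]:
    """Area (same units as ``cell_areas``) covered by each regime.

    The three classes partition the grid, so the returned areas sum to the
    total of ``cell_areas``.
    """
    mld_grid = np.asarray(mld_grid, dtype=float)
    ds_grid = np.asarray(ds_grid, dtype=float)
    cell_areas = np.asarray(cell_areas, dtype=float)
    p = params or RegimeParams()
    shallow = mld_grid < p.mld_threshold
    mw = shallow & (ds_grid > p.ds_threshold)
    ml = shallow & ~mw
    return {
        REGIME_MW: float(cell_areas[mw].sum()),
        REGIME_ML: float(cell_areas[ml].sum()),
        REGIME_UNSTRATIFIED: float(cell_areas[~shallow].sum()),
    }


# ---------------------------------------------------------------------------
# Export lag / retention
# ---------------------------------------------------------------------------

def export_lag(
    onset, flux_by_depth: dict[float, pd.Series]
) -> tuple[dict[float, pd.Timestamp], dict[float, float], float]:
    """Lag between bloom onset and the post-onset flux maximum per depth.

    Returns (peak date per depth, lag in 30.44-day months per depth,
    retention = lag at the deepest level). A monotone-decreasing flux peaks
    at onset (lag 0).
    """
    onset = pd.Timestamp(onset)
    peaks: dict[float, pd.Timestamp] = {}
    lags: dict[float, float] = {}
    for depth, series in flux_by_depth.items():
        post = series.loc[onset:].dropna()
        if post.empty:
            raise ValueError(f"no post-onset flux data at {depth} m")
        peak = pd.Timestamp(post.idxmax())
        peaks[depth] = peak
        lags[depth] = (peak - onset) / pd.Timedelta(days=DAYS_PER_MONTH)
    retention = lags[max(lags)] if lags else float("nan")
    return peaks, lags, retention


def summary_report(summary: BloomSummary) -> str:
    """Human-readable, table-style text rendering of a BloomSummary."""
    lines = [f"Bloom summary — {summary.regime} regime", "-" * 40]
    fmt_date = lambda d: "n/a (no crash)" if d is None else d.strftime("%d-%b-%Y")
    lines.append(f"Bloom start:      {fmt_date(summary.bloom_start)}")
    lines.append(f"Bloom end:        {fmt_date(summary.bloom_end)}")
    if summary.duration_months is not None:
        lines.append(f"Duration:         {summary.duration_months:.1f} months")
    if summary.growth_rate is not None:
        lines.append(f"Growth rate:      {summary.growth_rate:.2f} day-1 (e-folding)")
    for key, fits in summary.slopes.items():
        fit = fits["bloom"] if isinstance(fits, dict) else fits
        lines.append(f"Slope {key:18s} m={fit.m:+.3g} b={fit.b:.3g} r2={fit.r2:.3f}")
    for depth in sorted(summary.export_peak_dates):
        d = summary.export_peak_dates[depth]
        lag = summary.export_lags_months.get(depth)
        lines.append(f"Export peak {depth:6.0f} m: {d.strftime('%d-%b-%Y')} (lag {lag:.1f} mo)")
    if summary.retention_months is not None:
        lines.append(f"Retention:        {summary.retention_months:.1f} months to seafloor")
    return "\n".join(lines)
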