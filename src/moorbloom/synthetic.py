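"""Synthetic two-regime mooring datasets for exercising the full pipeline.

Generates hourly multi-depth sensor channels, daily surface heat flux,
sea-ice cover, sediment-trap POC fluxes and benthic oxygen consumption for
the two observed stratification regimes:

* ML (mixed-layer) regime: weak stratification over a ~50 m mixed layer;
  an intense diatom bloom starts 01-May when the surface heat flux turns
  positive, draws winter nitrate (12 umol/l) down to depletion by mid
  June, with oxygen, pCO2 and chlorophyll coupled to nitrate through fixed
  stoichiometric ratios (7 umol O2, ~6 umol C, 0.6 ug chl per umol NO3),
  and a fast, chlorophyll-rich export pulse reaching the 2600 m seafloor
  within 4-7 weeks of onset.

* MW (meltwater) regime: strong, shallow salinity stratification from ice
  melt confines production to a thin surface layer above the 30 m sensors;
  30-m channels stay nearly flat while PAR at 30 m drops by almost two
  orders of magnitude from shading, and seafloor export peaks months
  later (September-October), degraded.

The noiseless backbone is deterministic and exactly stoichiometrically
coupled; seeded AR(1) noise is additive on the backbone (multiplicative on
strictly positive channels), so channel statistics converge to the
backbone when averaging seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from moorbloom import light as light_mod


@dataclass
class ExportPulse:
    """One Gaussian POC-flux pulse: integral (g C m-2) around a peak date."""

    peak: str  # ISO date
    width_days: float
    integral_g: float


@dataclass
class Stoichiometry:
    o2_per_no3: float = 7.0  # umol O2 produced per umol NO3 taken up
    c_per_no3: float = 6.0  # umol C per umol NO3
    chl_per_no3: float = 0.6  # ug chl per umol NO3


@dataclass
class NoiseSpec:
    ar1_coeff: float = 0.9  # hourly lag-1 autocorrelation
    sd: dict = field(default_factory=lambda: {
        "nitrate": 0.3, "aou": 2.0, "pco2": 3.0, "chl_rel": 0.05,
        "par_rel": 0.2, "salinity": 0.02, "temperature": 0.05,
        "heat_flux": 30.0, "ice_conc": 5.0, "flux_rel": 0.10,
    })


@dataclass
class ScenarioConfig:
    """Parameterization of one synthetic regime year.

    Defaults reproduce the observed regime contrasts: bloom timings,
    winter nitrate, drawdown magnitudes, stoichiometric coupling and
    export-pulse integrals/lags.
    """

    regime: str = "ML"
    year: int = 2018
    bloom_start: str = "2018-05-01"
    bloom_end: str = "2018-06-15"
    winter_nitrate: float = 12.0  # umol l-1
    nitrate_floor: float = 0.0  # set in factory; chl_max = chl_per_no3 * drawdown
    chl_max: float = 7.0  # ug l-1 at 30 m (ML); MW 30-m channel stays low
    chl_sat_max: float = 7.0  # satellite surface-layer chlorophyll
    growth_rate: float = 0.2  # day-1 e-folding
    stoich: Stoichiometry = field(default_factory=Stoichiometry)
    pco2_winter: float = 400.0  # uatm
    pco2_drawdown: float = 180.0  # uatm
    par_shading_orders: float = 1.5  # log10 drop of 30-m PAR at bloom peak
    salinity_30m_winter: float = 34.9
    salinity_30m_summer_min: float = 34.7
    surface_salinity_min: float = 34.7  # MW: 30.5
    mld_winter: float = 265.0  # m (deep winter mixing)
    mld_bloom: float = 50.0  # m during stratified season
    exports: dict = field(default_factory=dict)  # depth -> list[ExportPulse]
    flux_background_mg: dict = field(default_factory=dict)  # depth -> mg/m2/day
    benthic_o2_base: float = 0.35  # mmol m-2 day-1
    benthic_o2_response: float = 0.0  # fractional rise after seafloor pulse
    ice_conc_max: float = 0.0  # percent
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if pd.Timestamp(self.bloom_start) >= pd.Timestamp(self.bloom_end):
            raise ValueError("bloom_start must precede bloom_end")
        if self.regime not in ("ML", "MW"):
            raise ValueError("regime must be 'ML' or 'MW'")

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (pd.Timestamp(f"{self.year}-01-01"),
                pd.Timestamp(f"{self.year}-12-31 23:00"))

    @property
    def nitrate_drawdown(self) -> float:
        return self.winter_nitrate - self.nitrate_floor


def ml_config(seed: int = 0) -> ScenarioConfig:
    """Default mixed-layer (2018-type) scenario.

    The nitrate floor is chosen so the chlorophyll ceiling equals
    ``chl_per_no3 * drawdown`` exactly (0.6 * 11.67 = 7.0 ug/l).
    """
    st = Stoichiometry()
    chl_max = 7.0
    return ScenarioConfig(
        regime="ML",
        year=2018,
        bloom_start="2018-05-01",
        bloom_end="2018-06-15",
        nitrate_floor=12.0 - chl_max / st.chl_per_no3,
        chl_max=chl_max,
        chl_sat_max=chl_max,
        pco2_drawdown=180.0,
        par_shading_orders=1.5,
        mld_bloom=45.0,
        exports={
            200.0: [ExportPulse("2018-05-18", 8.0, 3.0)],
            1200.0: [ExportPulse("2018-05-25", 9.0, 2.0)],
            2600.0: [ExportPulse("2018-06-08", 13.0, 1.18)],
        },
        flux_background_mg={200.0: 15.0, 1200.0: 13.0, 2600.0: 12.1},
        benthic_o2_response=0.5,
        ice_conc_max=0.0,
        seed=seed,
    )


def mw_config(seed: int = 0) -> ScenarioConfig:
    """Default meltwater (2017-type) scenario.

    30-m biogeochemical channels are nearly flat (production happens in a
    thin layer above the sensors): the 30-m nitrate dip is sized so AOU
    reaches ~-15 umol/l at the stoichiometric coupling; surface-layer
    (satellite) chlorophyll reaches 4 ug/l. Seafloor export peaks 01-Oct.
    """
    st = Stoichiometry()
    drawdown_30m = 15.0 / st.o2_per_no3  # ~2.14 umol/l
    return ScenarioConfig(
        regime="MW",
        year=2017,
        bloom_start="2017-05-10",
        bloom_end="2017-08-15",
        nitrate_floor=12.0 - drawdown_30m,
        chl_max=st.chl_per_no3 * drawdown_30m,  # ~1.3 ug/l at 30 m
        chl_sat_max=4.0,
        growth_rate=0.1,
        pco2_drawdown=50.0,
        par_shading_orders=1.9,
        salinity_30m_winter=34.9,
        salinity_30m_summer_min=33.5,
        surface_salinity_min=30.5,
        mld_bloom=10.0,
        exports={
            200.0: [ExportPulse("2017-08-15", 15.0, 1.5)],
            1200.0: [ExportPulse("2017-08-20", 15.0, 1.2)],
            2600.0: [ExportPulse("2017-10-01", 12.0, 1.46)],
        },
        flux_background_mg={200.0: 9.0, 1200.0: 8.0, 2600.0: 7.0},
        benthic_o2_response=0.0,
        ice_conc_max=75.0,
        seed=seed,
    )


def default_config(regime: str, seed: int = 0) -> ScenarioConfig:
    return ml_config(seed) if regime.upper() == "ML" else mw_config(seed)


# ---------------------------------------------------------------------------
# Backbone pieces
# ---------------------------------------------------------------------------

def bloom_progress(
    time: pd.DatetimeIndex, start, end, growth_rate: float, cap: float = 0.98
) -> np.ndarray:
    """Bloom progress in [0, 1]: logistic rise at the configured e-folding
    rate, clipped to a plateau of exactly 1 as the bloom completes.

    The logistic midpoint sits at 25/45 of the bloom duration, so the
    default ML bloom rises from a small winter background, turns over mid
    bloom, and saturates right at the bloom end.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    t_days = np.asarray((time - start) / pd.Timedelta(days=1), dtype=float)
    duration = (end - start) / pd.Timedelta(days=1)
    t_mid = 25.0 / 45.0 * duration
    logi = 1.0 / (1.0 + np.exp(-growth_rate * (t_days - t_mid)))
    return np.clip(logi / cap, 0.0, 1.0)


def _post_bloom_relax(
    time: pd.DatetimeIndex, sigma: np.ndarray, end, recovery_days: float = 120.0,
    floor: float = 0.35,
) -> np.ndarray:
    """Relax the bloom progress back toward ``floor`` after the bloom end
    (remineralization raises nitrate, AOU and pCO2 again)."""
    end = pd.Timestamp(end)
    t_after = np.asarray((time - end) / pd.Timedelta(days=1), dtype=float)
    out = sigma.copy()
    after = t_after > 0
    out[after] = np.maximum(
        floor, sigma[after] - (1.0 - floor) * t_after[after] / recovery_days
    )
    return out


def _chl_decay(time: pd.DatetimeIndex, sigma: np.ndarray, end,
               efold_days: float = 12.0) -> np.ndarray:
    """Chlorophyll crash: exponential decay of progress after the bloom end."""
    end = pd.Timestamp(end)
    t_after = np.asarray((time - end) / pd.Timedelta(days=1), dtype=float)
    out = sigma.copy()
    after = t_after > 0
    out[after] = sigma[after] * np.exp(-t_after[after] / efold_days)
    return out


def ar1_noise(n: int, coeff: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with lag-1 autocorrelation ``coeff`` and
    marginal standard deviation ``sd``."""
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - coeff**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = coeff * out[i - 1] + eps[i]
    return out


def seasonal_heat_flux(
    dates: pd.DatetimeIndex, onset, amplitude: float = 150.0, mean: float = 0.0
) -> np.ndarray:
    """Annual-cycle net surface heat flux (W m-2) crossing zero upward at
    the onset date (positive warms the ocean)."""
    onset = pd.Timestamp(onset)
    t_days = np.asarray((dates - onset) / pd.Timedelta(days=1), dtype=float)
    # daily values represent day-centre means, so the onset day itself is
    # already (just) positive
    return mean + amplitude * np.sin(2.0 * np.pi * (t_days + 0.5) / 365.0)


def exponential_chl(
    n_days: int = 14,
    rate: float = 0.2,
    chl0: float = 0.1,
    noise_sd: float = 0.1,
    seed: int | None = None,
    start: str = "2018-05-01",
) -> pd.Series:
    """Daily chlorophyll from the exponential early-bloom backbone
    ``chl0 * exp(rate * t)`` with multiplicative lognormal noise of the
    given log-sd (0 for noiseless)."""
    t = np.arange(n_days, dtype=float)
    chl = chl0 * np.exp(rate * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        chl = chl * np.exp(rng.normal(0.0, noise_sd, n_days))
    idx = pd.date_range(start, periods=n_days, freq="D")
    return pd.Series(chl, index=idx, name="chl")


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioDataset:
    """Everything one regime year produces, on its native time bases."""

    config: ScenarioConfig
    hourly: pd.DataFrame  # 30/55/265 m sensor channels
    daily: pd.DataFrame  # heat flux, ice, satellite chl, MLD, dS
    fluxes: pd.DataFrame  # daily POC flux per trap depth + benthic O2

    @property
    def regime(self) -> str:
        return self.config.regime


def _surface_par(time: pd.DatetimeIndex, latitude: float = 79.0) -> np.ndarray:
    """Hourly clear-sky surface PAR (umol m-2 s-1) from solar elevation;
    zero through the polar night."""
    doy = np.asarray(time.dayofyear, dtype=float)
    hour = np.asarray(time.hour, dtype=float)
    decl = np.radians(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.25))
    lat = np.radians(latitude)
    hang = np.radians((hour - 12.0) * 15.0)
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hang)
    ssr = 600.0 * np.maximum(sin_elev, 0.0)  # W m-2 clear-sky scale
    return light_mod.shortwave_to_par(ssr)


def generate_scenario(
    config: ScenarioConfig | None = None,
    regime: str | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> ScenarioDataset:
    """Generate one regime year of mutually consistent synthetic channels.

    Deterministic given the config seed; with ``noise=False`` the exact
    stoichiometrically coupled backbone is returned (the same backbone the
    noisy channels fluctuate around).
    """
    if config is None:
        config = default_config(regime or "ML", seed if seed is not None else 0)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t0, t1 = cfg.span
    hours = pd.date_range(t0, t1, freq="h")
    days = pd.date_range(t0.floor("D"), t1.floor("D"), freq="D")
    nh, nd = len(hours), len(days)
    st = cfg.stoich

    # --- bloom progress (30-m channels) ------------------------------------
    sigma_rise = bloom_progress(hours, cfg.bloom_start, cfg.bloom_end, cfg.growth_rate)
    sigma_nut = _post_bloom_relax(hours, sigma_rise, cfg.bloom_end)
    sigma_chl = _chl_decay(hours, sigma_rise, cfg.bloom_end)

    drawdown = cfg.nitrate_drawdown
    nitrate = cfg.winter_nitrate - drawdown * sigma_nut
    aou = -st.o2_per_no3 * drawdown * sigma_nut
    pco2 = cfg.pco2_winter - cfg.pco2_drawdown * sigma_nut
    chl30 = st.chl_per_no3 * drawdown * sigma_chl

    # --- light: clear-sky PAR attenuated to 30 m plus bloom shading --------
    par_surf = _surface_par(hours)
    shading = 10.0 ** (-cfg.par_shading_orders * sigma_chl)
    par30 = light_mod.par_at_depth(par_surf, 30.0) * shading

    # --- physical channels --------------------------------------------------
    doy = np.asarray(hours.dayofyear, dtype=float)
    summer = np.exp(-0.5 * ((doy - 200.0) / 55.0) ** 2)  # seasonal envelope
    temp30 = 2.0 + 1.2 * summer
    sal30 = cfg.salinity_30m_winter - (
        cfg.salinity_30m_winter - cfg.salinity_30m_summer_min
    ) * summer
    sal_surface = cfg.salinity_30m_winter - (
        cfg.salinity_30m_winter - cfg.surface_salinity_min
    ) * summer
    if cfg.regime == "MW":
        # intermittent meltwater advection pulses as early as March
        pre = (hours >= pd.Timestamp(f"{cfg.year}-03-01")) & (
            hours < pd.Timestamp(cfg.bloom_start)
        )
        pulse = 0.5 * (1 + np.sin(2 * np.pi * doy / 9.0))
        sal30 = np.where(pre, sal30 - 0.3 * pulse, sal30)
        sal_surface = np.where(pre, sal_surface - 1.0 * pulse, sal_surface)
    temp55 = 2.0 + 0.6 * summer
    sal55 = np.full(nh, 35.0)
    temp265 = np.full(nh, 2.0)
    sal265 = np.full(nh, 35.1)

    # --- noise ---------------------------------------------------------------
    def add(base: np.ndarray, key: str, relative: bool = False,
            floor: float | None = None) -> np.ndarray:
        if not noise:
            return np.asarray(base, dtype=float)
        sd = cfg.noise.sd.get(key, 0.0)
        eta = ar1_noise(len(base), cfg.noise.ar1_coeff, sd, rng)
        out = base * np.exp(eta) if relative else base + eta
        if floor is not None:
            out = np.maximum(out, floor)
        return out

    hourly = pd.DataFrame(
        {
            "temperature_30m": add(temp30, "temperature"),
            "salinity_30m": add(sal30, "salinity"),
            "salinity_surface": add(sal_surface, "salinity"),
            "temperature_55m": add(temp55, "temperature"),
            "salinity_55m": add(sal55, "salinity"),
            "temperature_265m": add(temp265, "temperature"),
            "salinity_265m": add(sal265, "salinity"),
            "nitrate_30m": add(nitrate, "nitrate", floor=0.0),
            "aou_30m": add(aou, "aou"),
            "pco2_30m": add(pco2, "pco2", floor=100.0),
            "chl_30m": add(chl30, "chl_rel", relative=True),
            "par_30m": add(par30, "par_rel", relative=True, floor=0.0),
        },
        index=hours,
    )

    # --- daily channels ------------------------------------------------------
    q_net = seasonal_heat_flux(days, cfg.bloom_start)
    if noise:
        q_net = q_net + ar1_noise(nd, 0.8, cfg.noise.sd["heat_flux"], rng)

    doy_d = np.asarray(days.dayofyear, dtype=float)
    if cfg.regime == "MW":
        # icy through winter/spring, melting out over the bloom
        melt = 1.0 / (1.0 + np.exp((doy_d - 175.0) / 12.0))
        ice_conc = cfg.ice_conc_max * melt
        ice_distance = -30.0 * melt + 60.0 * (1 - melt)
    else:
        ice_conc = np.zeros(nd)
        ice_distance = np.full(nd, 80.0) + 40.0 * np.sin(2 * np.pi * doy_d / 365.0)
    if noise and cfg.ice_conc_max > 0:
        ice_conc = np.clip(
            ice_conc + ar1_noise(nd, 0.8, cfg.noise.sd["ice_conc"], rng), 0.0, 100.0
        )

    sigma_sat = bloom_progress(
        days, cfg.bloom_start, cfg.bloom_end,
        cfg.growth_rate if cfg.regime == "ML" else 0.15,
    )
    chl_sat = cfg.chl_sat_max * _chl_decay(days, sigma_sat, cfg.bloom_end, 20.0)

    stratified = (days >= pd.Timestamp(cfg.bloom_start)) & (
        days <= pd.Timestamp(f"{cfg.year}-10-15")
    )
    mld_daily = np.where(np.asarray(stratified), cfg.mld_bloom, cfg.mld_winter)
    s100 = 35.0
    sal_surface_daily = pd.Series(sal_surface, index=hours).resample("D").mean()
    ds_daily = s100 - sal_surface_daily.reindex(days).to_numpy()

    daily = pd.DataFrame(
        {
            "heat_flux": q_net,
            "ice_conc": ice_conc,
            "ice_distance": ice_distance,
            "chl_sat": chl_sat,
            "mld": mld_daily,
            "ds_surface_100m": ds_daily,
        },
        index=days,
    )

    # --- export fluxes and benthic oxygen ------------------------------------
    fluxes = pd.DataFrame(index=days)
    t_days = np.arange(nd, dtype=float)
    for depth in sorted(cfg.exports):
        base = np.full(nd, cfg.flux_background_mg.get(depth, 0.0))
        for pulse in cfg.exports[depth]:
            peak_i = float((pd.Timestamp(pulse.peak) - days[0]) / pd.Timedelta(days=1))
            gauss = np.exp(-0.5 * ((t_days - peak_i) / pulse.width_days) ** 2)
            gauss *= pulse.integral_g * 1000.0 / (
                pulse.width_days * np.sqrt(2 * np.pi)
            )  # mg m-2 day-1
            base = base + gauss
        fluxes[f"poc_{int(depth)}m"] = add(base, "flux_rel", relative=True, floor=0.0)

    benthic = np.full(nd, cfg.benthic_o2_base)
    if cfg.benthic_o2_response > 0 and 2600.0 in cfg.exports:
        peak = pd.Timestamp(cfg.exports[2600.0][0].peak)
        lag_days = np.asarray((days - peak) / pd.Timedelta(days=1), dtype=float) - 5.0
        resp = np.where(
            lag_days > 0, np.exp(-lag_days / 60.0) * (1 - np.exp(-lag_days / 7.0)), 0.0
        )
        benthic = benthic * (1.0 + cfg.benthic_o2_response * resp)
    fluxes["benthic_o2"] = add(benthic, "flux_rel", relative=True, floor=0.0)

    return ScenarioDataset(config=cfg, hourly=hourly, daily=daily, fluxes=fluxes)


def generate_forcing(
    regime: str = "ML",
    span: tuple | None = None,
    seed: int = 0,
    freq: str = "6h",
    noise: bool = True,
    onset: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Meteorological forcing for the 1-D model plus the daily net heat flux.

    Returns ``(forcing, daily_q)``: a DataFrame of wind, non-penetrating
    heat, shortwave and evaporation-minus-precipitation records at ``freq``
    spacing, and the daily-mean net surface heat flux whose noiseless
    seasonal cycle crosses zero at the regime's bloom-onset date.
    """
    cfg = default_config(regime, seed)
    if onset is None:
        onset = cfg.bloom_start
    if span is None:
        span = cfg.span
    t0, t1 = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if (t1 - t0) < pd.Timedelta(days=60):
        raise ValueError("forcing span must cover at least 60 days")
    idx = pd.date_range(t0, t1, freq=freq)
    rng = np.random.default_rng(seed + 1)

    q_net = seasonal_heat_flux(idx, onset)
    doy = np.asarray(idx.dayofyear, dtype=float)
    q_sw = 180.0 * np.maximum(np.sin(2 * np.pi * (doy - 80.0) / 365.0), 0.0)
    q_nonpen = q_net - q_sw
    wind_u = np.full(len(idx), 5.0)
    wind_v = np.full(len(idx), 2.0)
    emp = np.full(len(idx), 1.0e-8)  # weak net evaporation
    if noise:
        n = len(idx)
        q_nonpen = q_nonpen + ar1_noise(n, 0.85, 25.0, rng)
        wind_u = wind_u + ar1_noise(n, 0.9, 2.5, rng)
        wind_v = wind_v + ar1_noise(n, 0.9, 2.5, rng)

    forcing = pd.DataFrame(
        {"wind_u": wind_u, "wind_v": wind_v, "q_nonpen": q_nonpen,
         "q_sw": q_sw, "emp": emp},
        index=idx,
    )
    daily_q = (forcing["q_nonpen"] + forcing["q_sw"]).resample("D").mean()
    daily_q.name = "heat_flux"
    return forcing, daily_q


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(dataset: ScenarioDataset, directory, netcdf: bool = False) -> Path:
    """Write a scenario to CSV files (+ optional NetCDF) with a manifest.

    The manifest records the full config including the seed, so a fixture
    is reproducible bit-for-bit from it.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("hourly", "daily", "fluxes"):
        getattr(dataset, name).to_csv(
            out / f"{name}.csv", index_label="time", float_format="%.17g"
        )
    if netcdf:
        import xarray as xr

        ds = xr.Dataset.from_dataframe(dataset.hourly.rename_axis("time"))
        ds.to_netcdf(out / "hourly.nc", engine="scipy")
    manifest = dataclasses.asdict(dataset.config)
    manifest["exports"] = {
        str(k): [dataclasses.asdict(p) for p in v]
        for k, v in dataset.config.exports.items()
    }
    manifest["flux_background_mg"] = {
        str(k): v for k, v in dataset.config.flux_background_mg.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def read_fixture(directory) -> ScenarioDataset:
    out = Path(directory)
    manifest = json.loads((out / "manifest.json").read_text())
    manifest["stoich"] = Stoichiometry(**manifest["stoich"])
    manifest["noise"] = NoiseSpec(**manifest["noise"])
    manifest["exports"] = {
        float(k): [ExportPulse(**p) for p in v]
        for k, v in manifest["exports"].items()
    }
    manifest["flux_background_mg"] = {
        float(k): v for k, v in manifest["flux_background_mg"].items()
    }
    cfg = ScenarioConfig(**manifest)
    frames = {}
    for name in ("hourly", "daily", "fluxes"):
        df = pd.read_csv(out / f"{name}.csv", index_col="time", parse_dates=True,
                         float_precision="round_trip")
        df.index.name = None
        frames[name] = df.astype(float)  # "%g" writes integral floats as ints
    return ScenarioDataset(config=cfg, **frames)
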