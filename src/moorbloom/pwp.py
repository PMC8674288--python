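"""Price-Weller-Pinkel (PWP) 1-D upper-ocean mixed-layer model.

Simulates the response of a T/S/momentum column to surface heat,
freshwater and wind forcing, ignoring horizontal gradients and advection.
Each time step applies, in order: surface fluxes (non-penetrating heat and
evaporation-minus-precipitation at the surface cell, shortwave absorbed
with a two-band exponential profile), convective adjustment (free
convection), wind-stress momentum input to the mixed layer and inertial
rotation, mixed-layer deepening while the bulk Richardson number is below
0.65, and relief of gradient-Richardson instability (< 0.25) by partial
mixing of adjacent cells.

Two idealized initial profiles represent the observed regimes: P17 (strong
meltwater halocline, surface salinity 30.5 rising linearly to 35 at 50 m)
and P18 (weak gradient, 34.8 to 35 over the same depth); both continue
linearly to 35.1 at 200 m at a constant temperature of 2 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from moorbloom.seawater import _density_atm

RHO0 = 1026.0  # kg m-3 reference for flux deposition
CP = 4190.0  # J kg-1 K-1
RHO_AIR = 1.22
DRAG_COEFF = 1.2e-3
SW_BANDS = ((0.6, 0.62), (20.0, 0.38))  # (absorption length m, fraction)
RB_CRIT = 0.65  # bulk Richardson number threshold
RG_CRIT = 0.25  # gradient Richardson number threshold
RG_STIR = 0.30  # post-mixing gradient Richardson target
LATITUDE_DEFAULT = 79.0  # degN, Fram Strait mooring latitude
G = 9.81


@dataclass
class ProfileState:
    """Uniform-grid T/S/velocity column (z positive down, cell centres)."""

    z: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z", "temperature", "salinity", "u", "v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.z)
        if any(len(getattr(self, k)) != n for k in ("temperature", "salinity", "u", "v")):
            raise ValueError("profile arrays must share one length")
        dz = np.diff(self.z)
        if n > 1 and not np.allclose(dz, dz[0]):
            raise ValueError("grid must be uniform")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 1.0

    def sigma(self) -> np.ndarray:
        """Potential density anomaly (kg m-3, reference 0 dbar)."""
        return _density_atm(self.salinity, self.temperature) - 1000.0

    def copy(self) -> "ProfileState":
        return ProfileState(
            self.z.copy(), self.temperature.copy(), self.salinity.copy(),
            self.u.copy(), self.v.copy(),
        )


@dataclass
class ForcingRecord:
    """One surface-forcing sample."""

    wind_u: float  # m s-1 eastward 10-m wind
    wind_v: float  # m s-1 northward
    q_nonpen: float  # W m-2 longwave+sensible+latent, positive warms ocean
    q_sw: float  # W m-2 shortwave, positive down
    emp: float = 0.0  # m s-1 evaporation minus precipitation


@dataclass
class ScenarioSpec:
    profile_id: str  # P17 or P18
    forcing_id: str = "synthetic"
    days: float = 75.0


@dataclass
class PWPParams:
    dt: float = 900.0  # s
    dz: float = 1.0  # m
    depth: float = 250.0  # m
    latitude: float = LATITUDE_DEFAULT
    drag_coeff: float = DRAG_COEFF
    rb_crit: float = RB_CRIT
    rg_crit: float = RG_CRIT
    sw_bands: tuple = SW_BANDS

    @property
    def coriolis(self) -> float:
        return 2 * 7.2921e-5 * np.sin(np.radians(self.latitude))


PROFILES = {
    "P17": ([0.0, 50.0, 200.0, 1000.0], [30.5, 35.0, 35.1, 35.1]),
    "P18": ([0.0, 50.0, 200.0, 1000.0], [34.8, 35.0, 35.1, 35.1]),
}


def make_profile(profile_id: str, params: PWPParams | None = None) -> ProfileState:
    """Idealized initial profile P17 (meltwater) or P18 (weak gradient)."""
    if profile_id not in PROFILES:
        raise ValueError(f"unknown profile {profile_id!r}; choose P17 or P18")
    p = params or PWPParams()
    z = np.arange(p.dz / 2.0, p.depth, p.dz)
    s_z, s_v = PROFILES[profile_id]
    return ProfileState(
        z=z,
        temperature=np.full_like(z, 2.0),
        salinity=np.interp(z, s_z, s_v),
        u=np.zeros_like(z),
        v=np.zeros_like(z),
    )


def mld_from_profile(state: ProfileState, threshold: float = 0.05) -> float:
    """Mixed-layer depth: shallowest cell exceeding the surface density by
    ``threshold`` kg m-3 (the same density criterion the observational MLD
    estimator uses between instruments)."""
    sig = state.sigma()
    above = np.flatnonzero(sig - sig[0] > threshold)
    if above.size == 0:
        return float(state.z[-1])
    return float(state.z[above[0]])


def _mix(state: ProfileState, k: int) -> None:
    """Homogenize cells 0..k (inclusive) in place."""
    sl = slice(0, k + 1)
    for arr in (state.temperature, state.salinity, state.u, state.v):
        arr[sl] = arr[sl].mean()


def _convective_adjust(state: ProfileState) -> int:
    """Relieve static instability by deepening surface mixing; returns the
    index of the last cell inside the mixed layer."""
    k = 0
    sig = state.sigma()
    n = len(sig)
    # running sums keep the repeated layer means O(1)
    sum_t, sum_s = state.temperature[0], state.salinity[0]
    while k < n - 1:
        ml_sig = _density_atm(sum_s / (k + 1), sum_t / (k + 1)) - 1000.0
        if ml_sig > sig[k + 1] + 1e-12:
            k += 1
            sum_t += state.temperature[k]
            sum_s += state.salinity[k]
        else:
            break
    if k > 0:
        _mix(state, k)
    return k


def _bulk_richardson_deepen(state: ProfileState, k: int, rb_crit: float) -> int:
    """Entrain cells while the bulk Richardson number of the layer is
    subcritical: Rb = g * dRho * h / (rho0 * dV^2)."""
    n = len(state.z)
    while k < n - 1:
        sig_pair = _density_atm(
            state.salinity[k : k + 2], state.temperature[k : k + 2]
        )
        h = state.z[k] + state.dz / 2.0
        drho = sig_pair[1] - sig_pair[0]
        du = state.u[k + 1] - state.u[k]
        dv = state.v[k + 1] - state.v[k]
        dv2 = du**2 + dv**2
        if dv2 < 1e-12:
            break
        rb = G * drho * h / (RHO0 * dv2)
        if rb >= rb_crit:
            break
        k += 1
        _mix(state, k)
    return k


def _gradient_richardson_relieve(
    state: ProfileState, rg_crit: float, max_sweeps: int = 60
) -> None:
    """Partially mix adjacent cells where the gradient Richardson number is
    subcritical, targeting RG_STIR after each stir.

    Each sweep stirs every subcritical interface once (in order, using
    updated values), which converges in a handful of sweeps.
    """
    dz = state.dz
    for _ in range(max_sweeps):
        sig = state.sigma()
        drho = np.diff(sig)
        shear2 = (np.diff(state.u) ** 2 + np.diff(state.v) ** 2) / dz**2
        with np.errstate(divide="ignore", invalid="ignore"):
            rg = np.where(
                shear2 > 1e-14, (G / RHO0) * (drho / dz) / shear2, np.inf
            )  # no shear -> no shear instability
        bad = np.flatnonzero(rg < rg_crit)
        if bad.size == 0:
            return
        for j in bad:
            f = 1.0 - max(float(rg[j]), 0.0) / RG_STIR
            f = min(max(f, 0.0), 1.0)
            for arr in (state.temperature, state.salinity, state.u, state.v):
                d = 0.5 * f * (arr[j] - arr[j + 1])
                arr[j] -= d
                arr[j + 1] += d


def _remove_interior_inversions(state: ProfileState, max_sweeps: int = 50) -> None:
    """Mix away residual interior density inversions (e.g. the tiny warming
    of the bottom cell that absorbs the deep shortwave remainder), which
    sit below the surface mixed layer and are invisible to surface-down
    convective adjustment."""
    for _ in range(max_sweeps):
        sig = state.sigma()
        bad = np.flatnonzero(np.diff(sig) < 0.0)
        if bad.size == 0:
            return
        for j in bad:
            for arr in (state.temperature, state.salinity, state.u, state.v):
                pair_mean = 0.5 * (arr[j] + arr[j + 1])
                arr[j] = arr[j + 1] = pair_mean


def step(state: ProfileState, forcing: ForcingRecord, params: PWPParams | None = None) -> ProfileState:
    """Advance the column by one time step; returns a new state."""
    p = params or PWPParams()
    for name in ("wind_u", "wind_v", "q_nonpen", "q_sw", "emp"):
        if not np.isfinite(getattr(forcing, name)):
            raise ValueError(f"non-finite forcing field {name}")
    st = state.copy()
    dz, dt = st.dz, p.dt

    # (1) surface heat + freshwater, shortwave two-band absorption
    st.temperature[0] += forcing.q_nonpen * dt / (RHO0 * CP * dz)
    if forcing.q_sw != 0.0:
        z_top = st.z - dz / 2.0
        z_bot = st.z + dz / 2.0
        absorbed = np.zeros_like(st.z)
        for length, frac in p.sw_bands:
            absorbed += frac * (np.exp(-z_top / length) - np.exp(-z_bot / length))
        absorbed[-1] += 1.0 - absorbed.sum()  # remainder absorbed at depth
        st.temperature += forcing.q_sw * absorbed * dt / (RHO0 * CP * dz)
    # virtual salt flux: evaporation concentrates surface salinity
    st.salinity[0] += st.salinity[0] * forcing.emp * dt / dz

    # (2) convective adjustment
    k = _convective_adjust(st)

    # (3) wind stress into the mixed layer, then inertial rotation
    wind_speed = float(np.hypot(forcing.wind_u, forcing.wind_v))
    tau_x = RHO_AIR * p.drag_coeff * wind_speed * forcing.wind_u
    tau_y = RHO_AIR * p.drag_coeff * wind_speed * forcing.wind_v
    h_ml = st.z[k] + dz / 2.0
    st.u[: k + 1] += tau_x * dt / (RHO0 * h_ml)
    st.v[: k + 1] += tau_y * dt / (RHO0 * h_ml)
    ang = p.coriolis * dt
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    u_new = cos_a * st.u + sin_a * st.v
    v_new = -sin_a * st.u + cos_a * st.v
    st.u, st.v = u_new, v_new

    # (4) bulk-Richardson deepening, (5) gradient-Richardson relief
    k = _bulk_richardson_deepen(st, k, p.rb_crit)
    _gradient_richardson_relieve(st, p.rg_crit)
    _remove_interior_inversions(st)
    return st


@dataclass
class RunResult:
    time: pd.DatetimeIndex
    mld: np.ndarray  # m
    heat_content: np.ndarray  # J m-2 relative to t0
    salt_content: np.ndarray  # psu*m relative to t0
    states: list = field(default_factory=list)


def run(
    profile: ProfileState | str,
    forcing: pd.DataFrame,
    params: PWPParams | None = None,
    output_interval_hours: float = 6.0,
    keep_states: bool = False,
    start_time=None,
) -> RunResult:
    """Integrate the model over a forcing record.

    ``forcing`` is a DataFrame indexed by time with columns wind_u, wind_v,
    q_nonpen, q_sw, emp; it is linearly interpolated to the model step.
    Diagnostics (MLD by the density-threshold criterion, heat and salt
    content changes) are recorded every ``output_interval_hours``.
    """
    p = params or PWPParams()
    st = make_profile(profile, p) if isinstance(profile, str) else profile.copy()
    t0 = pd.Timestamp(start_time) if start_time is not None else forcing.index[0]
    t_end = forcing.index[-1]
    n_steps = int(np.floor((t_end - t0) / pd.Timedelta(seconds=p.dt)))

    f_time = (forcing.index - forcing.index[0]) / pd.Timedelta(seconds=1)
    f_time = np.asarray(f_time, dtype=float)
    cols = {c: forcing[c].to_numpy(dtype=float) for c in
            ("wind_u", "wind_v", "q_nonpen", "q_sw", "emp")}

    def forcing_at(t_s: float) -> ForcingRecord:
        return ForcingRecord(**{c: float(np.interp(t_s, f_time, v)) for c, v in cols.items()})

    dz = st.dz
    heat0 = float((RHO0 * CP * st.temperature * dz).sum())
    salt0 = float((st.salinity * dz).sum())
    out_every = max(1, int(round(output_interval_hours * 3600.0 / p.dt)))

    times, mlds, heats, salts, states = [], [], [], [], []

    def record(i: int) -> None:
        times.append(t0 + pd.Timedelta(seconds=i * p.dt))
        mlds.append(mld_from_profile(st))
        heats.append(float((RHO0 * CP * st.temperature * dz).sum()) - heat0)
        salts.append(float((st.salinity * dz).sum()) - salt0)
        if keep_states:
            states.append(st.copy())

    record(0)
    for i in range(1, n_steps + 1):
        st = step(st, forcing_at((i - 0.5) * p.dt), p)
        if i % out_every == 0 or i == n_steps:
            record(i)

    return RunResult(
        time=pd.DatetimeIndex(times),
        mld=np.asarray(mlds),
        heat_content=np.asarray(heats),
        salt_content=np.asarray(salts),
        states=states,
    )


def integrated_surface_heat(forcing: pd.DataFrame, t0, t1) -> float:
    """Time integral of total surface heat input (J m-2) over [t0, t1],
    with the same linear-in-time interpolation the model uses."""
    q = (forcing["q_nonpen"] + forcing["q_sw"]).astype(float)
    t_s = np.asarray((forcing.index - forcing.index[0]) / pd.Timedelta(seconds=1), float)
    a = (pd.Timestamp(t0) - forcing.index[0]) / pd.Timedelta(seconds=1)
    b = (pd.Timestamp(t1) - forcing.index[0]) / pd.Timedelta(seconds=1)
    grid = np.linspace(a, b, 20001)
    vals = np.interp(grid, t_s, q.to_numpy())
    return float(np.trapezoid(vals, grid))


def read_forcing_csv(path) -> pd.DataFrame:
    """Read a forcing table (time, wind_u, wind_v, q_nonpen, q_sw, emp)."""
    df = pd.read_csv(path, parse_dates=["time"]).set_index("time")
    missing = {"wind_u", "wind_v", "q_nonpen", "q_sw"} - set(df.columns)
    if missing:
        raise ValueError(f"forcing file missing columns: {sorted(missing)}")
    if "emp" not in df.columns:
        df["emp"] = 0.0
    return df
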