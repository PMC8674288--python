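# Methods

This note records the models, parameter choices and numerical decisions
behind `moorbloom`, and what the synthetic-data tests do and do not
demonstrate about real mooring records.

## Scope and measurement model

The package assumes the observing system of a deep Arctic mooring pair:
fixed-depth recorders near 30, 55 and 265 m (T, S, O₂, PAR, chlorophyll
fluorescence, backscatter, nitrate, pCO₂, pH), daily gridded sea-ice
concentration/drift, surface heat-flux series from a reanalysis, sediment
traps at 200/1200 m, and a seafloor lander with a trap and oxygen
microprofiler at ~2600 m. Because nothing profiles the upper 30 m, several
quantities are deliberately one-sided: the mixed-layer depth is a
*minimum* bound, and 30-m biogeochemistry under strong meltwater
stratification sits below the productive layer and is flagged as
non-representative of it.

## Conditioning

Bursts of k ∈ {5, 8, 10} one-second samples are averaged linearly to one
hourly value stamped at the burst hour. Blow-downs (instruments dragged
down by currents, excursions up to ~200 m) are flagged when the
pressure-derived depth exceeds the nominal depth by more than 10 m — deep
enough that mooring tilt and tide never trigger it, shallow enough that
any real blow-down does. The low-pass filter is a 4th-order Butterworth
with half-power at (5 days)⁻¹, applied forward–backward (`filtfilt`) so it
is zero-phase and preserves the record mean; gaps ≤ 6 h are linearly
interpolated first, longer gaps propagate as missing and their segments
are filtered independently. Daily means require ≥ 6 valid hourly samples.
Masked samples never enter any downstream statistic.

## Seawater physics

Density uses the EOS-80/UNESCO 1983 polynomial on practical salinity —
matching what the conductivity sensors report — with potential temperature
from the Fofonoff Runge–Kutta descent. The two-sensor buoyancy frequency
is N² = (g/ρ₀)(ρ_lower − ρ_upper)/Δz from potential densities (stable >
0); the thermal and haline parts use α and β from centered finite
differences of the EOS at the mean T/S of the pair. The decomposition
closes to within 5 % for |ΔT| ≤ 3 °C, |ΔS| ≤ 1 (property-tested over that
grid); the residual is EOS nonlinearity. Oxygen saturation is the García &
Gordon (1992) Benson–Krause fit (ml/l scale, converted at 44.66 µmol/ml);
AOU = saturation − measured, with no pressure correction (surface
equilibration convention). The meltwater fraction is a two-endmember
salinity balance with defaults S_source = 35.1 (Atlantic Water) and
S_ice = 8 (bulk sea ice); both are exposed in config because they are
assumptions, chosen so a 30.5 surface salinity corresponds to a meltwater
contribution of ~1/6 by volume.

## Minimum mixed-layer depth

For each lower instrument, Δσ against the uppermost sensor is corrected by
subtracting the pair's 0.5th percentile over the deployment, so corrected
differences are ≥ 0 for 99.5 % of samples. This removes small calibration
offsets, and its premise is that every pair sees near-zero Δσ at some
point (deep winter mixing); on a permanently stratified record it would
eat real signal, so `percentile=None` disables it. The hourly estimate is
the deepest instrument with corrected Δσ < 0.05 kg m⁻³, or 0 if none
qualifies — the data cannot bound the MLD from above. The daily value is
the 4th-smallest hourly value (exactly 3 shallower, 21 deeper),
deliberately biased toward states that keep phytoplankton in the surface
layer; with n < 24 valid hours the allowed shallower count scales as
⌈3n/24⌉, preserving the fractional bias. Output is always 0 or an
instrument depth, never interpolated.

## Light

Constants: detection floor 10⁻¹·³² µmol m⁻² s⁻¹, shortwave→PAR 2.1
(µmol m⁻² s⁻¹)/(W m⁻²), clear-water k_d = 0.02 m⁻¹. The mixed-layer
average PAR uses the closed form PAR_surf(1 − e^(−k_d·MLD))/(k_d·MLD) with
the limit PAR_surf as MLD → 0. The euphotic depth is a power law
z_eu = 34.0 · chl^(−0.39); the coefficients are this package's calibration
to two anchor points (20 m at 4 µg l⁻¹, ~16 m at 7 µg l⁻¹) rather than a
published case-1-water fit, and are config-exposed. Day length comes from
the standard sunrise equation with the low-precision solar declination;
refraction is ignored, so the polar-day/night boundaries are sharp.

## Carbonate system

Alkalinity comes from the regional linear relation Alk = 736 + 45.2·S
(µmol kg⁻¹). DIC is solved from pCO₂ and alkalinity with fixed nutrient
concentrations (phosphate 0.5, silicate 5 µmol l⁻¹, converted to per-mass
with in-situ density): [CO₂*] = K₀·pCO₂ fixes the carbonate terms up to
[H⁺], and Brent's method finds the pH in [3, 12] where total alkalinity
(carbonate + borate + water + phosphate + silicate − H⁺) balances.
Constants (total pH scale, chosen for cold S = 30–35 water): K₀ Weiss
1974; K₁/K₂ Lueker et al. 2000; K_B Dickson 1990; K_W and the
phosphoric/silicic constants Millero 1995; boron/salinity Uppström 1974.
The inverse route (pCO₂ from DIC and Alk) uses the same constants, and the
round trip closes far below 1 µatm. With these constants,
DIC(pCO₂ = 400 µatm, Alk = 2318, T = 2 °C, S = 35) ≈ 2189 µmol kg⁻¹
(DIC/Alk ≈ 0.94, typical of cold surface water), and a 180 µatm drawdown
at fixed Alk/T/S corresponds to ΔDIC ≈ 97 µmol kg⁻¹; the unit tests pin
these to an independent dense-grid bisection oracle rather than to any
nominal value. Bloom carbon takeup is DIC(onset) − DIC(argmin pCO₂), and
the 130 µatm sensor bias correction is applied as a config-driven constant
offset over one deployment window, never auto-detected.

## Phenology and budgets

Bloom onset is the first date from which the daily net surface heat flux
stays positive for ≥ 5 consecutive days (persistence guards against
winter-time excursions; the run is extended back to the first day of the
uninterrupted positive stretch). Bloom end is the first post-onset day
with nitrate < 1 µmol l⁻¹; a bloom that never depletes nitrate (the
meltwater case) has no end date. Growth rates are least-squares slopes of
ln(chl) over a window, excluding non-positive values with a warning.
Stoichiometric coupling is summarized by OLS fits of daily averages over
the bloom window (and a second post-bloom window) for nitrate/pCO₂/
chlorophyll against AOU and chlorophyll against nitrate. Regime
classification: MW if MLD < 50 m and ΔS > 1 (surface minus 100 m
salinity), ML if MLD < 50 m otherwise, else unstratified; equality at the
ΔS boundary goes to ML because both printed inequalities are strict. In
the end-to-end pipeline the classification uses the *median* MLD and ΔS
over the bloom window, which is robust to a noise-jittered onset pulling a
few winter days into the window. Durations and export lags are reported in
30.44-day mean months. The three production estimates use Redfield
C:N = 106:16 with a carbon molar mass of 12.011, DIC drawdown converted to
volume with in-situ density, and a carbon:chlorophyll mass ratio of 50
(range 6–60).

## Sea ice

Distances are great circles on a spherical Earth (R = 6371 km). The edge
threshold is a strict 20 % exceedance; the signed distance is positive
from open water to the nearest ice cell and negative from ice to the
nearest open-water cell. Gate export integrates (drift normal to the
gate) × (concentration fraction) along the gate polyline, sampling each
segment at sub-cell spacing with nearest-cell fields; gate orientation and
the export-positive side are explicit metadata. Cells with missing drift
are skipped.

## PWP 1-D mixed-layer model

The model advances T/S/U/V on a uniform 1 m grid over 250 m at dt = 15 min
through the classical sequence: surface heat and freshwater deposition
(shortwave absorbed in two exponential bands, 0.6 m/62 % and 20 m/38 %,
with the sub-grid remainder absorbed in the bottom cell), convective
adjustment, wind-stress momentum into the mixed layer (bulk drag
C_d = 1.2 × 10⁻³, ρ_air = 1.22) with inertial rotation at 79° N, bulk-
Richardson deepening at R_b < 0.65, and gradient-Richardson relief at
R_g < 0.25 by partial pair mixing toward R_g = 0.30 (Gauss–Seidel sweeps
over all subcritical interfaces). A final sweep removes any residual
interior inversion (e.g. from the deep shortwave remainder), which
surface-down convection cannot see. All thresholds are config-exposed;
they are the canonical values for this model family, since only the model
itself, not its numerics, is specified by the observational analysis it
supports. Column heat and salt closures against time-integrated surface
fluxes hold to ≪ 0.1 %, static stability holds after every step, and
halving dz moves the final MLD by < 2 m on the test runs. Under identical
seasonal forcing the meltwater profile P17 (30.5 → 35 over 50 m) keeps its
MLD an order of magnitude shallower than the weak-gradient P18
(34.8 → 35): wind mixing alone cannot break the meltwater halocline.

## Synthetic scenarios: what they are and are not

The generator produces one full regime year of mutually consistent
channels from a single "bloom progress" curve: a logistic rise at the
configured e-folding rate (0.2 day⁻¹ ML, 0.1 MW), clipped to a plateau of
exactly 1 as the bloom completes, with a linear post-bloom relaxation for
nitrate/AOU/pCO₂ (remineralization) and an exponential crash for
chlorophyll. Nitrate falls from the winter value (12 µmol l⁻¹) by a
configured drawdown; AOU, pCO₂ and chlorophyll are *exact* linear
functions of the same progress (7 µmol O₂, 180 µatm/11.67 µmol NO₃, and
0.6 µg chl per µmol NO₃ in the ML defaults), so the regression operators
have a known ground truth. Two consequences are worth stating: the ML
chlorophyll ceiling (7 µg l⁻¹) equals 0.6 × the nitrate drawdown by
construction, and the exact 7:1 coupling implies a synthetic AOU minimum
near −82 µmol l⁻¹ — the printed regime summary's "integrated AOU ≈ −60"
is not arithmetically consistent with both the full nitrate drawdown and
the 7:1 ratio, and the generator resolves the conflict in favor of the
coupling, which is what the regression targets measure. Similarly, with
the depletion threshold at 1 µmol l⁻¹ the ML bloom end is detected ~1 week
before the nominal 15-Jun crash date; the nominal date is kept in the
scenario config.

Export is a constant background plus Gaussian pulses per trap depth,
parameterized by peak date, width and integral, with the ML seafloor pulse
(~1.2 g C m⁻², σ = 13 d, peak 38 d after onset) sized so the seasonal
integrals reproduce the observed contrasts (ML 3.4/1.1, MW 1.3/2.1
g C m⁻² for Mar–Aug/Sep–Nov) and the event reads ~35 mg m⁻² day⁻¹ for
about a month. The MW seafloor peak sits at 01-Oct. Because the two
regimes are different calendar years, peak-timing differences are compared
as day-of-year.

Noise is stationary AR(1) (hourly lag-1 coefficient 0.9) added to the
backbone — multiplicative (lognormal) on strictly positive channels —
with per-channel SDs at realistic sensor levels (e.g. nitrate 0.3
µmol l⁻¹, pCO₂ 3 µatm, chlorophyll 5 %, daily heat flux 30 W m⁻²).
Averaging across seeds converges to the backbone.

What passing tests show: the operators implement their definitions
exactly, recover known couplings under realistic noise, and the pipeline's
qualitative regime contrast is driven by the stated mechanisms. What they
do not show: skill on real records, where sensors drift nonlinearly,
advection aliases the budgets (the generator has no advective events),
noise is non-stationary, and the stoichiometry is only approximately
linear. The synthetic channels are a harness, not a simulation of ocean
physics.

## Problem sizes

The default test suite generates regime years at hourly resolution
(8760 samples × ~15 channels), runs the 1-D model for 75 days at
dt = 15 min twice for the profile comparison and shorter spans for
conservation and refinement checks, and cross-checks the MLD estimator on
1000 random stacks — about two minutes end to end. The acceptance script
generates four scenario years and completes in well under a minute.
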