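# moorbloom

Year-round moored-sensor analysis of Arctic phytoplankton bloom regimes.

In the Fram Strait marginal ice zone, the fate of the spring bloom hinges on
whether sea-ice meltwater is present when the productive season starts.
Meltwater leaves a very strong, shallow salinity stratification (the
**meltwater / MW regime**): production is squeezed into a thin surface
layer, grazing and export are weak, and carbon is retained in the upper
ocean for months. Without meltwater (the **mixed-layer / ML regime**) a
weakly stratified ~50 m layer hosts a short, intense diatom bloom that
strips winter nitrate in about six weeks and delivers a fast,
chlorophyll-rich pulse of particulate organic carbon (POC) to the 2600 m
seafloor within 4–7 weeks of onset.

`moorbloom` is a toolkit for doing this kind of analysis from hourly moored
sensor records (T, S, pressure, O₂, PAR, chlorophyll fluorescence, optical
backscatter, nitrate, pCO₂), gridded sea-ice products, sediment traps and
benthic landers. It is aimed at observational oceanographers and
biogeochemists who want the derived quantities, the phenology, and the
budgets — without profiling instruments.

## What it computes

* **Conditioning** (`timeseries`): burst averaging, blow-down masking,
  zero-phase 5-day low-pass, daily means; CSV and NetCDF I/O.
* **Seawater physics** (`seawater`): EOS-80 potential density; two-sensor
  buoyancy frequency `N² = (g/ρ₀)·Δρ/Δz` with its thermal/haline split
  `N²_T = g·α·ΔT/Δz`, `N²_S = −g·β·ΔS/Δz`; apparent oxygen utilization
  `AOU = O₂,sat(T,S) − O₂`; meltwater fraction from a two-endmember
  salinity balance.
* **Mixed-layer depth** (`mld`): the *minimum* MLD from discrete-depth
  recorders — deepest instrument with Δσ < 0.05 kg m⁻³ after a
  per-deployment 0.5th-percentile offset correction; daily values as the
  4th-smallest hourly realization (3 shallower / 21 deeper).
* **Light** (`light`): detection-limit floor (10⁻¹·³² µmol m⁻² s⁻¹),
  shortwave→PAR (2.1 µmol m⁻² s⁻¹ per W m⁻²), exponential attenuation
  (k_d = 0.02 m⁻¹), mixed-layer-averaged PAR
  `PAR_avail = PAR_surf·(1−e^(−k_d·MLD))/(k_d·MLD)`, a chlorophyll
  power-law euphotic depth, and the sunrise equation.
* **Carbonate system** (`carbonate`): Alk = 736 + 45.2·S; DIC from pCO₂ and
  alkalinity by solving the full equilibrium (Lueker 2000 constants, total
  pH scale); bloom carbon takeup as ΔDIC between onset and the pCO₂
  minimum; the constant-offset pCO₂ bias correction.
* **Nutrients & budgets** (`nutrients`): N* = NO₃ − 16·PO₄,
  Si* = Si − NO₃; SUNA drift correction (2.4 µmol l⁻¹ yr⁻¹); column stocks
  and the three production estimates (Redfield 106:16 from nitrate, ΔDIC,
  chlorophyll × C:Chl = 50).
* **Optics** (`chl_optics`): fluorometer factor-2 bias; per-second
  backscatter aggregation flags (> 0.002 m⁻¹ sr⁻¹).
* **Phenology** (`phenology`): bloom onset when the surface heat flux stays
  positive; bloom end at nitrate depletion; e-folding growth rates;
  least-squares stoichiometric slopes (AOU, pCO₂, chlorophyll vs.
  nitrate); regime classification (MW: MLD < 50 m and ΔS > 1); export lags
  and retention.
* **Sea ice** (`seaice`): percent ice days (> 20 %), signed distance to the
  ice edge, gate area-export integrals.
* **PWP model** (`pwp`): a Price–Weller–Pinkel 1-D mixed-layer model with
  the idealized meltwater (P17) and weak-gradient (P18) initial profiles.
* **Synthetic data** (`synthetic`): a generator that emulates both regime
  years — exact stoichiometric coupling, seeded AR(1) noise — so the whole
  pipeline runs and is tested without any downloads.

## Worked example

```python
from moorbloom import synthetic, pipeline, phenology

ml = synthetic.generate_scenario(regime="ML", noise=False)
summary = pipeline.summarize_scenario(ml)
print(phenology.summary_report(summary))
```

prints

```
Bloom summary — ML regime
----------------------------------------
Bloom start:      01-May-2018
Bloom end:        08-Jun-2018
Duration:         1.2 months
Growth rate:      0.19 day-1 (e-folding)
Slope aou_vs_nitrate     m=+7 b=-84 r2=1.000
Slope aou_vs_pco2        m=+0.454 b=-181 r2=1.000
Slope aou_vs_chl         m=-11.7 b=-1.78e-14 r2=1.000
Slope chl_vs_nitrate     m=-0.6 b=7.2 r2=1.000
Export peak    200 m: 18-May-2018 (lag 0.6 mo)
Export peak   1200 m: 25-May-2018 (lag 0.8 mo)
Export peak   2600 m: 08-Jun-2018 (lag 1.2 mo)
Retention:        1.2 months to seafloor
```

The onset lands where the net surface heat flux turns positive; the bloom
crashes when nitrate drops below 1 µmol l⁻¹; the slope of AOU against
nitrate is the 7:1 molar oxygen:nitrate coupling of the early bloom, and
chlorophyll rises 0.6 µg l⁻¹ per µmol l⁻¹ nitrate consumed. The seafloor
export pulse peaks 5½ weeks after onset. The same chain on the MW scenario
reports no bloom crash, a ~4.7-month retention, and an autumn seafloor
peak.

The same operations are exposed on the command line:

```sh
moorbloom simulate --regime mw --seed 42 --out fixtures/mw/
moorbloom phenology --scenario ml --noiseless
moorbloom pwp --profile P17 --days 75
moorbloom condition input.csv output.csv --cutoff-days 5
```

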