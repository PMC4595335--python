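# aridet

Daily crop evapotranspiration and soil-water balance for arid irrigation
districts.

In the irrigation districts of arid northwest China, almost no runoff is
generated: the dominant hydrological process is irrigation followed by
evapotranspiration (ET). `aridet` simulates that cycle for a district of
hydrological response units (HRUs) — each a soil type × crop × irrigation
schedule combination — and answers the planning question behind it: *how do
district-scale crop ET and farm income respond when the planting pattern
changes?*

The package is aimed at agro-hydrologists and irrigation planners who work
from Python. Everything is importable; `examples/` holds one short script
per capability, and a thin `aridet` CLI wraps the common runs.

## The model

Each HRU is a layered soil bucket advanced daily:

```
SW_t = SW_{t-1} + (P + I) − Q_surf − E_a − w_seep − Q_gw
```

with precipitation `P`, irrigation `I`, actual ET `E_a`, and percolation
below the profile `w_seep` (all mm; `Q_surf` and `Q_gw` are zero by default
in this flat, fully irrigated setting). Two ET partitions are provided:

**Original (SWAT-style) module.** Potential ET `E0` first evaporates
canopy-intercepted water; the residual `E0'` drives an LAI-gated maximum
transpiration `Et = E0'·LAI/3` (for `LAI ≤ 3`, else `E0'`) and a soil
evaporation demand distributed over depth by
`f(z) = z / (z + exp(2.374 − 0.00713 z))` — so 50% of soil evaporation
comes from the top 10 mm and 95% from the top 100 mm — with ESCO-controlled
compensation between layers. The actual ET takes the smaller of demand and
what each store can supply.

**Dual crop coefficient module (FAO-56).** Crop ET is
`ETc = (Kcb + Ke)·ET0`, where the basal coefficient `Kcb` follows the
four-segment seasonal curve through the tabulated stage values, climate
adjusted by `[0.04(u2−2) − 0.004(RHmin−45)]·(h/3)^0.3`, and the soil
evaporation coefficient is `Ke = Kr·(Kcmax − Kcb)`. The drying-reduction
coefficient `Kr` comes in two forms: the classic FAO two-stage depletion
form (`Kr = 1` until the readily evaporable water REW is used, then
`(TEW − De)/(TEW − REW)`), and a surface-soil-water form
`Kr = (FC − St)/(FC − 0.5·WP)` over the 100-mm evaporation layer, which is
the default because it needs only the simulated surface water state. Note
the second form gives `Kr = 0` at field capacity — the inverse of the FAO
stage-1 behaviour; see `docs/methods.md`.

Reference ET comes from FAO-56 Penman–Monteith (default), Priestley–Taylor
or Hargreaves, or a measured `et0_obs` column in the weather file.

Around the simulator: district planting-scenario aggregation, a crop
output-value account (net value = yield × price − input cost), model-skill
metrics (RE, R², Nash–Sutcliffe) with the standard acceptance gates
(|RE| < 20%, R² > 0.6, Ens > 0.5), LH-OAT parameter sensitivity screening,
and a seeded stochastic weather generator for the district's climate
(~155 mm/yr precipitation, 80–85% in April–September, 7.7 °C mean).

## Worked example

```bash
python examples/03_scenarios_and_economics.py
```

prints (synthetic weather, seed 7, six years with one spin-up year):

```
district mean annual crop ET (synthetic weather):
  current    :  519.2 mm
  scenario 1 :  516.7 mm
  scenario 2 :  508.2 mm

total net output value (10^6 yuan):
  current    :  142.99
  scenario 1 :  138.31
  scenario 2 :  154.13
  scenario 1 vs current: -3.28%
  scenario 2 vs current: +7.79%
```

Scenario 1 cuts the spring-wheat share from 40% to 20%; scenario 2 cuts
the summer-maize share from 30% to 9.5% (total cultivated area fixed at
23 393.1 hm²). Both lower district ET because the two grain crops are the
heaviest water users; net output value falls under scenario 1 but rises
7.79% under scenario 2, which shifts land to potato — the crop with the
highest net value per hectare (15 688 yuan/hm²).

Other examples: `01_reference_et.py` (ET0 methods), `02_hru_season.py`
(one maize season, both modules), `04_metrics_and_sensitivity.py` (skill
metrics, gates, LH-OAT), `05_weather_generator.py` (climate recovery).

## CLI

```bash
aridet genweather --years 10 --seed 1 --out w.csv
aridet simulate --weather w.csv --module dualkc --crop "Summer maize" --out sim.csv
aridet scenario --weather w.csv --out scen.csv
aridet economics
aridet sensitivity --n-strata 10 --seed 1
aridet metrics --sim sim_monthly.csv --obs obs_monthly.csv
```

Exit codes: 0 success, 2 validation error, 3 numerical failure.

## File formats

Weather CSV columns: `date` (ISO), `precip` (mm), `tmax`, `tmin` (°C),
`rh_mean`, `rh_min` (%), `wind_u2` (m/s at 2 m), optional `solar`
(MJ m⁻² d⁻¹) and `et0_obs` (mm/d). Soil CSV: `soil, depth_bottom_mm,
bulk_density_g_cm3, awc, ksat_mm_h, clay_pct, silt_pct, sand_pct`.
Packaged district tables (soils, irrigation quotas, basal crop
coefficients, scenario proportions, economics, parameter ranges) live in
`src/aridet/data/` and load via `aridet.load_fixture_tables()`. Simulation
output is one row per day with the full water-balance ledger
(`et0, etc_demand, et_act, transp, evap, ecan, precip, irrigation, seep,
sw_total, closure_err`).

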