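# Methods

## Scope and structure

`aridet` simulates the irrigation–evapotranspiration cycle of an arid
irrigation district as a set of independent hydrological response units
(HRUs): one layered soil bucket per soil type × crop × irrigation schedule,
advanced on a daily step. District quantities are area-proportion-weighted
aggregates over crops, with each crop's ET averaged over the soil types it
grows on. There is no routing between HRUs, no canal conveyance, no
groundwater store and no crop-yield response to water: yields, prices and
input costs enter the economics as constants.

## Daily sequence

For each day, in order:

1. crop development (day of season → LAI, height, rooting depth);
2. canopy interception of rainfall into a store of capacity
   `canmx · LAI/LAI_max` (mm); water held beyond a shrinking capacity
   drips back to the soil;
3. scheduled irrigation and throughfall infiltrate into the top layer
   (no runoff: border/furrow irrigation on flat fields);
4. reference ET (FAO-56 Penman–Monteith by default);
5. the selected ET module computes demands and extracts what the stores
   can supply (details below);
6. percolation: water above field capacity drains layer-to-layer at
   `excess · (1 − exp(−24/TT))`, `TT = (SAT − FC)/Ksat` hours; water above
   saturation overflows immediately; bottom-layer drainage leaves the
   profile as seepage.

Every daily record carries a closure residual
`ΔSW + Δcanopy − (P + I − E_a − seep)`; the simulator aborts if it ever
exceeds 10⁻⁶ mm. In practice residuals sit at the 10⁻¹³ mm level (float
summation noise), so conservation is structural, not fitted.

## The two ET modules

**Original (SWAT-style).** Canopy water evaporates first (all of the
demand if the store suffices, else the whole store). The residual demand
`E0'` is split between an LAI-gated maximum transpiration
(`E0'·LAI/3` for LAI ≤ 3, else `E0'`) and a potential soil evaporation
`E0'·exp(−0.5·LAI)`, cross-limited in the standard way so the joint demand
never exceeds `E0'`. Soil-evaporation demand is distributed over depth by
`f(z) = z/(z + exp(2.374 − 0.00713 z))`. The constant 2.374 is the one
that reproduces the distribution's two defining anchors — 50% of
evaporation from 0–10 mm and 95% from 0–100 mm; a printed variant of the
constant (2.347) circulates in the literature and is accepted via the
`const` argument, but it misses the 50% anchor (it gives 0.51). Layer
demand is `es_max·(f(z_bottom) − esco·f(z_top))`, clamped at zero and
cumulative-capped at `es_max`: lowering ESCO lets deeper layers compensate
for a dry surface. Extraction per layer is limited to water above half the
wilting-point equivalent. Transpiration is distributed over the root zone
by the exponential profile `1 − exp(−10·z/z_root)` with EPCO-weighted
compensation of unmet upper-layer demand, never taking a layer below its
wilting point.

**Dual crop coefficient (FAO-56).** `ETc = (Kcb + Ke)·ET0`. The tabulated
`Kcb` follows the four-segment seasonal curve (constant initial, linear
development, constant mid, linear late). Climate adjustment adds
`[0.04(u2 − 2) − 0.004(RHmin − 45)]·(h/3)^0.3` with `u2` clamped to
[1, 6] m/s and `RHmin` to [20, 80]% (FAO validity ranges); the adjusted
value is a distinct type so it cannot be adjusted twice.
`Kcmax = max(1.2 + climate term, Kcb + 0.05)` and `Ke = Kr·(Kcmax − Kcb)`.
Two notes on fidelity to the source formulation this module follows:

* The crop-coefficient identity is implemented as `Kc = Kcb + Ke`
  (the standard FAO-56 form); a variant writing the ET0 factor inside the
  coefficient is dimensionally inconsistent with `ETc = Kc·ET0` and is not
  reproduced.
* The default drying coefficient is the surface-water form
  `Kr = (FC − St)/(FC − 0.5·WP)` over the Ze = 100 mm evaporation layer
  (`St` is the top soil layer's water rescaled to Ze). This form needs no
  depletion bookkeeping, which is its point — but it is *inverted*
  relative to FAO stage-1 behaviour: it yields `Kr = 0` when the surface
  is at field capacity (wet) and `Kr = 1` when dried to half wilting
  point. It is implemented exactly as defined; the classic two-stage FAO
  form (`Kr = 1` while `De ≤ REW`, then `(TEW − De)/(TEW − REW)`) is a
  switch away (`kr_method="fao"`). In irrigated settings the practical
  consequence is that the modified form suppresses the post-wetting
  evaporation flush and spreads soil evaporation into dry-down periods,
  which produces smoother ET series.
* The exposed/wetted-fraction factor `few` of the full FAO procedure is
  omitted, matching the formulation implemented (Ke has no such factor).

In dual-Kc mode, intercepted canopy water evaporates first against the Ke
demand; the soil part is limited by surface water above `0.5·WP`;
transpiration demand `Kcb·ET0` is extracted with the same root-profile
machinery as the original module (EPCO active). The FAO root-zone stress
factor Ks (depletion fraction p = 0.55) exists behind `stress=True` and is
off by default — the district is fully irrigated and the hard
wilting-point bound already prevents overdraft.

TEW is `(FC − 0.5·WP)·Ze`; REW defaults to `0.45·TEW` bounded to
[2, 10] mm, representative of the FAO tabulation across the textures
involved (sandy soils get ~3 mm, loams ~9 mm).

## Parameters

| name | meaning | range | default | active in |
|---|---|---|---|---|
| `esco` | soil-evaporation compensation (depth distribution) | 0–1 | 0.875 | original |
| `canmx` | maximum canopy interception, mm | 0–30 | 9.853 | both |
| `gw_revap` | groundwater re-evaporation coefficient | 0.02–0.2 | 0.115 | none (inert) |
| `epco` | plant-uptake compensation | 0–1 | 0.827 | both |
| `sol_awc_scale` | relative AWC adjustment | −0.5–0.5 | 0 | both |

Defaults are the district calibration values. `gw_revap` is accepted for
interface completeness only: with no groundwater store it influences
nothing, and its LH-OAT effect is zero by construction — a deliberate
divergence from the published rank of that parameter, which presupposes a
groundwater module. `sol_awc_scale` rescales every layer's available water
capacity and re-pins FC = WP + AWC. Because ESCO acts through the layer
compensation that the dual-Kc formulation replaces, sensitivity screening
uses the original module, where all four evaporation parameters act.

## Soil water constants

The soil table gives AWC but not FC/WP. The wilting point is estimated
from texture by the linear rule `WP = 0.0263 + 0.00505·clay%` (volumetric,
a Saxton–Rawls-style regression truncated to the clay term, which is what
the district's texture range supports), and FC is pinned to `WP + AWC`:
the measured AWC is authoritative, the pedotransfer only anchors its
position. Both can be overridden per layer. Derived FC is validated
against porosity (from bulk density, particle density 2.65 g/cm³). One
packaged sierozem layer's printed texture percentages sum to 120%; the
table is transcribed as printed (the water constants depend only on the
clay fraction) and the texture-sum check is lenient for loaded survey
tables, strict for directly constructed layers.

## Crop phenology (assumed)

The published tables give stage-wise basal crop coefficients and
irrigation quotas but no planting dates, stage lengths, heights, LAI or
rooting depths. The packaged phenology is therefore an explicit assumption
set (flagged in `data/phenology.csv`): spring-sown calendar typical of the
Shiyang River basin, with stage lengths chosen so every scheduled
irrigation date falls inside its crop's season (e.g. spring wheat planted
25 March, 25/30/45/25-day stages; summer maize 20 April,
25/40/50/30). LAI rises linearly to its maximum over the initial +
development stages, holds through mid-season, and declines to 20% of
maximum through late season; height grows over the same window; roots
deepen linearly to their maximum by the end of development. These shapes
control the canopy/soil partition and interception capacity, not the
Kcb curve itself.

## Synthetic weather

The generator targets the district's stated climate: mean annual
precipitation 155 mm with 82.5% in April–September, mean temperature
7.7 °C. Occurrence is a two-state Markov chain with monthly parameters;
wet-day amounts are exponential, with monthly means set so the stationary
wet-day frequency times the mean amount reproduces the monthly
climatological totals in expectation. Temperature is a sinusoid (half
range 13.5 °C, peak mid-July) plus Gaussian noise; the diurnal range is
Gaussian (mean 13 °C, floored at 4 °C, damped on wet days); humidity is
higher on wet days (dry-day mean RH 45%); wind is lognormal with mean
2 m/s. Solar radiation is left unset and estimated from the diurnal range
(Hargreaves rule, kRs = 0.16 for an interior site).

What the generator does *not* emulate: interannual persistence (droughts,
wet spells), dust-storm and frost events, trends over 1960–2011, and any
correlation between wind and temperature. Passing tests on this forcing
therefore demonstrate internal consistency (conservation, ordering,
determinism, climate recovery), not agreement with the historical record:
district ET levels on synthetic weather come out around 510–520 mm/yr,
below the ~620 mm reported from the historical forcing, and the ET
separation between crops is compressed, so scenario ET reductions are
directionally right but smaller in magnitude.

## Numerical choices

* Closure tolerance 10⁻⁶ mm/day (hard failure beyond it); all water moves
  by explicit transfers, so no clamp residues arise.
* Initial soil water at field capacity (irrigated district); the first
  simulated year is discarded as spin-up by default; a wilting-point
  start is available for supply-limited experiments.
* The water-balance identity is implemented with losses subtracting;
  ET demand in excess of storage is truncated, never borrowed.
* Economics: scenario areas are reported at 0.1 hm² with sum-preserving
  largest-remainder rounding so each scenario's areas add exactly to the
  23 393.1 hm² district (plain per-crop rounding misses one published
  cell by 0.1); per-crop money values use the rounded areas; percent
  changes are computed from unrounded totals and reported half-up at two
  decimals.
* LH-OAT: Latin-hypercube stratified base points; elementary effect
  `|100·(M₊ − M₀)/mean(M₊, M₀)/f|` with f = 0.05 by default (the source
  method's fraction is not published; 0.05 is configurable); when the
  mean magnitude is below 10⁻¹², the normalization switches to absolute
  differences; perturbations that would leave the parameter box flip
  direction; ties rank by declaration order; fully seeded.
* Nash–Sutcliffe is implemented unbounded below (the mathematically
  correct range), although it is often described as 0–1; gate logic is
  unaffected.

## Problem sizes

The test suite and the acceptance script run the district as 28 HRUs
(7 crops × 4 soil types, soil shares 0.30/0.40/0.10/0.20) over 10
synthetic years for conservation and scenario checks, 3–6 years for unit
and example runs, and 50 years for weather-generator climate recovery —
sizes chosen so the full pipeline exercises every code path while a
complete run stays in the seconds-to-a-minute range on one core.

## Known limitations

* No surface runoff or canal seepage; an SCS-style storm-runoff option is
  deliberately not included because the district's forcing almost never
  produces infiltration excess at daily resolution.
* No groundwater interaction: capillary rise, which the real district's
  shallow water table may supply, is absent — one reason simulated ET
  under-runs the reported historical level.
* The modified Kr form's inversion (dry surface → more evaporation) is
  faithful to its definition but physically debatable; use
  `kr_method="fao"` for the standard behaviour.
* Phenology is assumed, not measured; crop-specific conclusions should be
  re-run with local calendars.
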