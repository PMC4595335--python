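"""Daily soil-water bookkeeping and the HRU/district simulation loops.

Each hydrological response unit (HRU) is a layered soil bucket under one
crop and one irrigation schedule. The daily sequence is: canopy
interception → irrigation and infiltration → reference ET → module-specific
ET partition (original SWAT-style or dual crop coefficient) limited by what
each store can supply → percolation. Surface runoff and groundwater return
flow are zero by default: the district is flat, border/furrow irrigated and
has no simulated groundwater store, so every balance term is explicit and
the closure residual is tracked per day.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import phenology
from .et_dualkc import dualkc_step, surface_state, update_depletion
from .et_swat import (
    CanopyState,
    canopy_capacity,
    intercept_rainfall,
    original_et_step,
    plant_uptake_by_layer,
)
from .reference_et import Site, reference_et
from .types import (
    HRU,
    ModelParams,
    NumericalError,
    Scenario,
    SoilProfile,
    ValidationError,
    WeatherDay,
)

CLOSURE_TOL_MM = 1e-6
logger = logging.getLogger("aridet")


@dataclass
class SoilWaterState:
    """Mutable per-HRU state: layer water (mm), canopy store, Ke depletion."""

    sw_by_layer: list[float]
    canopy: CanopyState
    de: float = 0.0
    t: int = 0


def initial_state(profile: SoilProfile, initial: str = "fc") -> SoilWaterState:
    """Starting soil water: field capacity (default, irrigated district) or
    wilting point (``initial="wp"``)."""
    if initial not in ("fc", "wp"):
        raise ValidationError(f"initial must be 'fc' or 'wp', got {initial!r}")
    frac = "fc" if initial == "fc" else "wp"
    sw = [getattr(ly, frac) * profile.thickness(i) for i, ly in enumerate(profile.layers)]
    return SoilWaterState(sw_by_layer=sw, canopy=CanopyState(0.0, 0.0))


def water_balance_step(
    sw0: float,
    precip: float,
    irrigation: float,
    ea: float,
    qsurf: float = 0.0,
    seep: float = 0.0,
    qgw: float = 0.0,
) -> tuple[float, float]:
    """One bookkeeping step of the bucket balance.

    ``SW_t = SW_0 + (precip + irrigation) − qsurf − ea − seep − qgw``
    with losses subtracting. If the store cannot meet the ET demand, ea is
    truncated to what is available (the balance still closes); a negative
    store arising from the other fluxes is a numerical failure.

    Returns (new storage, actual ea).
    """
    for name, v in [
        ("precip", precip), ("irrigation", irrigation), ("ea", ea),
        ("qsurf", qsurf), ("seep", seep), ("qgw", qgw),
    ]:
        if v < 0:
            raise ValidationError(f"negative flux {name}={v}")
    sw = sw0 + precip + irrigation - qsurf - seep - qgw
    if sw < -CLOSURE_TOL_MM:
        raise NumericalError(
            f"non-ET fluxes drive storage negative ({sw:.6f} mm): "
            f"sw0={sw0}, qsurf={qsurf}, seep={seep}, qgw={qgw}"
        )
    ea_actual = min(ea, max(sw, 0.0))
    return max(sw, 0.0) - ea_actual, ea_actual


def percolate(profile: SoilProfile, sw_by_layer: list[float]) -> tuple[list[float], float]:
    """Gravity drainage through the profile; returns (new layers, seepage mm).

    Water above a layer's field capacity drains to the layer below at the
    storage-routing rate ``excess·(1 − exp(−24/TT))`` with travel time
    ``TT = (SAT − FC)/Ksat`` hours; water above saturation overflows
    immediately. Drainage from the bottom layer leaves the profile.
    """
    sw = list(sw_by_layer)
    n = len(profile.layers)
    inflow = 0.0
    seep = 0.0
    for i, ly in enumerate(profile.layers):
        thick = profile.thickness(i)
        sat_mm = ly.porosity * thick
        fc_mm = ly.fc * thick
        sw[i] += inflow
        inflow = 0.0
        overflow = max(sw[i] - sat_mm, 0.0)
        sw[i] -= overflow
        excess = max(sw[i] - fc_mm, 0.0)
        tt_hours = (sat_mm - fc_mm) / ly.ksat
        drain = excess * (1.0 - math.exp(-24.0 / tt_hours)) if tt_hours > 0 else excess
        sw[i] -= drain
        moved = overflow + drain
        if i + 1 < n:
            inflow = moved
        else:
            seep += moved
    return sw, seep


def irrigation_depth(schedule, date: dt.date) -> float:
    """Scheduled application depth (mm) on this calendar date, else 0."""
    return math.fsum(ev.depth for ev in schedule if (ev.month, ev.day) == (date.month, date.day))


def apply_irrigation(schedule, date: dt.date, state: SoilWaterState) -> float:
    """Add any scheduled quota to the topsoil; returns the depth applied."""
    depth = irrigation_depth(schedule, date)
    if depth > 0:
        state.sw_by_layer[0] += depth
    return depth


@dataclass
class SimResult:
    """Daily simulation records for one HRU plus aggregation helpers."""

    hru_id: str
    crop: str
    soil: str
    daily: pd.DataFrame
    spinup_years: int = 0

    def _active(self) -> pd.DataFrame:
        df = self.daily
        if self.spinup_years:
            years = sorted(df["date"].dt.year.unique())
            keep = years[self.spinup_years:]
            df = df[df["date"].dt.year.isin(keep)]
        return df

    def annual(self) -> pd.DataFrame:
        """Per-year sums of the water-balance fluxes (spin-up removed)."""
        df = self._active()
        g = df.groupby(df["date"].dt.year)
        return g[["et_act", "et0", "precip", "irrigation", "seep", "transp", "evap", "ecan"]].sum()

    def monthly(self) -> pd.DataFrame:
        """Per-month flux sums (spin-up removed)."""
        df = self._active()
        g = df.groupby([df["date"].dt.year.rename("year"), df["date"].dt.month.rename("month")])
        return g[["et_act", "et0", "precip", "irrigation"]].sum()

    @property
    def mean_annual_et(self) -> float:
        return float(self.annual()["et_act"].mean())

    @property
    def max_closure_error(self) -> float:
        return float(self.daily["closure_err"].abs().max())


def simulate_hru(
    hru: HRU,
    weather: list[WeatherDay],
    params: ModelParams = ModelParams(),
    module: str = "dualkc",
    kr_method: str = "modified",
    et0_method: str = "pm",
    site: Site = Site(),
    spinup: int = 1,
    stress: bool = False,
    initial: str = "fc",
) -> SimResult:
    """Run the daily loop for one HRU over a weather series.

    ``module`` selects the ET partition: ``"original"`` (SWAT-style canopy /
    LAI-gated transpiration / depth-distributed soil evaporation) or
    ``"dualkc"`` (FAO-56 dual crop coefficient; ``kr_method`` picks the
    drying-reduction form). ``stress`` enables the FAO root-zone water
    stress factor Ks (depletion fraction p = 0.55) on transpiration in
    dual-Kc mode; by default transpiration is limited only by the hard
    wilting-point bound, since the district is fully irrigated.
    """
    if module not in ("original", "dualkc"):
        raise ValidationError(f"unknown module {module!r}; use 'original' or 'dualkc'")
    profile = _apply_awc_scale(hru.soil, params.sol_awc_scale)
    crop = hru.crop
    state = initial_state(profile, initial)
    records: list[dict] = []
    for day in weather:
        dos = phenology.day_of_season(crop, day.date)
        lai_now = phenology.lai(crop, dos)
        h_now = phenology.height(crop, dos)
        rd = phenology.root_depth(crop, dos)
        sw_before = math.fsum(state.sw_by_layer) + state.canopy.storage

        # canopy interception of rainfall; water held beyond a shrinking
        # capacity (declining LAI) drips to the soil surface
        cap = canopy_capacity(params.canmx, lai_now, crop.lai_max)
        drip = max(state.canopy.storage - cap, 0.0)
        state.canopy = CanopyState(state.canopy.storage - drip, cap)
        throughfall, state.canopy = intercept_rainfall(day.precip, state.canopy)
        throughfall += drip

        # irrigation + infiltration into the topsoil
        irr = irrigation_depth(hru.schedule, day.date)
        state.sw_by_layer[0] += throughfall + irr

        et0 = reference_et(day, site, et0_method)

        if module == "original":
            result, transp_ly, esoil_ly, state.canopy = original_et_step(
                et0, lai_now, rd, state.canopy, profile, state.sw_by_layer, params
            )
            for i, (tr, ev) in enumerate(zip(transp_ly, esoil_ly)):
                state.sw_by_layer[i] -= tr + ev
            ecan, transp_act, evap_act = result.ecan, result.transp, result.esoil
            etc_demand = result.e0
            kcb = ke_coef = float("nan")
        else:
            surf = surface_state(profile, state.sw_by_layer[0], state.de)
            res = dualkc_step(
                et0, crop, dos, day.wind_u2, day.rh_min, h_now, surf, kr_method
            )
            # intercepted water evaporates first, against the Ke demand
            ecan = min(state.canopy.storage, res.evap)
            state.canopy = CanopyState(state.canopy.storage - ecan, state.canopy.capacity)
            evap_demand = res.evap - ecan
            evap_avail = max(surf.st_surface - 0.5 * surf.wp_mm, 0.0)
            evap_act = min(evap_demand, evap_avail)
            state.sw_by_layer[0] -= evap_act

            transp_demand = res.transp
            if stress:
                transp_demand *= _ks_factor(profile, state.sw_by_layer, rd)
            transp_ly = plant_uptake_by_layer(
                transp_demand, profile, rd, params.epco, state.sw_by_layer
            )
            transp_act = math.fsum(transp_ly)
            for i, tr in enumerate(transp_ly):
                state.sw_by_layer[i] -= tr
            state.de = update_depletion(surf, evap_act, throughfall + irr).de
            etc_demand = res.etc
            kcb, ke_coef = res.kcb, res.ke

        state.sw_by_layer, seep = percolate(profile, state.sw_by_layer)
        state.t += 1

        et_act = ecan + transp_act + evap_act
        sw_after = math.fsum(state.sw_by_layer) + state.canopy.storage
        closure = (sw_after - sw_before) - (day.precip + irr - et_act - seep)
        records.append(
            {
                "date": day.date,
                "et0": et0,
                "etc_demand": etc_demand,
                "et_act": et_act,
                "transp": transp_act,
                "evap": evap_act,
                "ecan": ecan,
                "kcb": kcb,
                "ke": ke_coef,
                "precip": day.precip,
                "irrigation": irr,
                "seep": seep,
                "sw_total": math.fsum(state.sw_by_layer),
                "closure_err": closure,
            }
        )
        logger.debug(
            "%s %s et0=%.3f et=%.3f sw=%.1f", hru.id, day.date, et0, et_act,
            math.fsum(state.sw_by_layer),
        )
        if abs(closure) > CLOSURE_TOL_MM:
            raise NumericalError(
                f"HRU {hru.id} {day.date}: water balance closure error {closure:.3e} mm"
            )
    daily = pd.DataFrame.from_records(records)
    daily["date"] = pd.to_datetime(daily["date"])
    for year, grp in daily.groupby(daily["date"].dt.year):
        logger.info(
            "HRU %s year %d: ET %.1f mm (ET0 %.1f, P %.1f, I %.1f, seep %.1f)",
            hru.id, year, grp["et_act"].sum(), grp["et0"].sum(),
            grp["precip"].sum(), grp["irrigation"].sum(), grp["seep"].sum(),
        )
    n_years = len({d.date.year for d in weather})
    eff_spinup = spinup if n_years > spinup else 0
    return SimResult(
        hru_id=hru.id, crop=crop.name, soil=profile.name, daily=daily, spinup_years=eff_spinup
    )


def _apply_awc_scale(profile: SoilProfile, scale: float) -> SoilProfile:
    """Relative AWC adjustment: awc → awc·(1+scale), FC re-pinned to WP + AWC."""
    if scale == 0.0:
        return profile
    from dataclasses import replace

    layers = tuple(
        replace(ly, awc=ly.awc * (1.0 + scale), fc=ly.wp + ly.awc * (1.0 + scale))
        for ly in profile.layers
    )
    return SoilProfile(name=profile.name, layers=layers, ze=profile.ze)


def _ks_factor(profile: SoilProfile, sw: list[float], root_depth: float, p: float = 0.55) -> float:
    """FAO root-zone water stress coefficient Ks in [0, 1]."""
    taw = raw_avail = 0.0
    tops = profile.layer_tops
    for i, ly in enumerate(profile.layers):
        top = tops[i]
        if top >= root_depth:
            break
        frac = (min(ly.depth_bottom, root_depth) - top) / profile.thickness(i)
        thick = profile.thickness(i)
        taw += (ly.fc - ly.wp) * thick * frac
        raw_avail += max(sw[i] - ly.wp * thick, 0.0) * frac
    if taw <= 0:
        return 1.0
    dr = taw - raw_avail
    raw = p * taw
    if dr <= raw:
        return 1.0
    return max((taw - dr) / (taw - raw), 0.0)


# ---------------------------------------------------------------------------
# district aggregation

DEFAULT_SOIL_SHARES = {
    "Grey desert soil": 0.30,
    "Irrigated desert soil": 0.40,
    "Aeolian sandy soil": 0.10,
    "Sierozem": 0.20,
}


def build_district_hrus(
    soils: dict[str, SoilProfile],
    crops: dict,
    schedules: dict,
    soil_shares: dict[str, float] | None = None,
    total_area: float = 23393.1,
) -> list[HRU]:
    """One HRU per (crop, soil) pair, areas split by the soil shares.

    Crop-level areas are attached later by the scenario proportions, so the
    per-HRU area here carries only the soil weighting within each crop.
    """
    shares = soil_shares or DEFAULT_SOIL_SHARES
    if abs(math.fsum(shares.values()) - 1.0) > 1e-9:
        raise ValidationError("soil shares must sum to 1")
    hrus = []
    for ci, (cname, crop) in enumerate(crops.items()):
        for si, (sname, share) in enumerate(shares.items()):
            hrus.append(
                HRU(
                    id=f"{cname}/{sname}",
                    area=total_area * share / len(crops),
                    soil=soils[sname],
                    crop=crop,
                    schedule=schedules[cname],
                    subdivision_id=str(si + 1),
                )
            )
    return hrus


def crop_annual_et(
    hrus: list[HRU],
    results: dict[str, SimResult],
    soil_shares: dict[str, float] | None = None,
) -> dict[str, pd.Series]:
    """Soil-share-weighted annual ET series per crop (mm/year)."""
    shares = soil_shares or DEFAULT_SOIL_SHARES
    by_crop: dict[str, pd.Series] = {}
    for hru in hrus:
        series = results[hru.id].annual()["et_act"] * shares[hru.soil.name]
        by_crop[hru.crop.name] = by_crop.get(hru.crop.name, 0.0) + series
    return by_crop


def apply_scenario(scenario: Scenario, crop_et: dict[str, float]) -> float:
    """District crop ET (mm): proportion-weighted mean of per-crop annual ET."""
    missing = [c for c in scenario.proportions if c not in crop_et]
    if missing:
        raise ValidationError(f"scenario {scenario.name!r}: unknown crop(s) {missing}")
    return math.fsum(p * crop_et[c] for c, p in scenario.proportions.items())


@dataclass
class DistrictResult:
    """Per-scenario district ET plus the underlying per-HRU simulations."""

    hru_results: dict[str, SimResult]
    crop_et_series: dict[str, pd.Series]
    scenario_et_series: dict[str, pd.Series]

    @property
    def scenario_mean_et(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.scenario_et_series.items()}

    @property
    def crop_mean_et(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.crop_et_series.items()}


def simulate_district(
    hrus: list[HRU],
    weather: list[WeatherDay],
    params: ModelParams = ModelParams(),
    scenarios: dict[str, Scenario] | None = None,
    soil_shares: dict[str, float] | None = None,
    **sim_kwargs,
) -> DistrictResult:
    """Simulate every HRU once and aggregate per planting scenario.

    Per-crop annual ET is independent of the scenario (proportions only
    reweight areas), so each (crop, soil) HRU is simulated a single time.
    """
    results = {hru.id: simulate_hru(hru, weather, params, **sim_kwargs) for hru in hrus}
    crop_series = crop_annual_et(hrus, results, soil_shares)
    scen_series: dict[str, pd.Series] = {}
    for name, scen in (scenarios or {}).items():
        parts = [crop_series[c] * p for c, p in scen.proportions.items() if p > 0]
        scen_series[name] = sum(parts)
    return DistrictResult(
        hru_results=results, crop_et_series=crop_series, scenario_et_series=scen_series
    )
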