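"""Soil-water bookkeeping, percolation, irrigation and the simulation loops."""

import datetime as dt
import math

import pytest

from aridet import (
    HRU,
    ModelParams,
    NumericalError,
    Scenario,
    SoilLayer,
    ValidationError,
    apply_scenario,
    build_profile,
    percolate,
    simulate_district,
    simulate_hru,
    water_balance_step,
)
from aridet.water_balance import (
    SoilWaterState,
    apply_irrigation,
    build_district_hrus,
    initial_state,
    irrigation_depth,
)


def two_layer_profile():
    layers = [
        SoilLayer(depth_bottom=200, bulk_density=1.4, awc=0.15, ksat=12.0,
                  clay=15.0, silt=40.0, sand=45.0),
        SoilLayer(depth_bottom=600, bulk_density=1.5, awc=0.12, ksat=6.0,
                  clay=20.0, silt=40.0, sand=40.0),
    ]
    return build_profile("two-layer", layers)


class TestWaterBalanceStep:
    def test_identity_with_zero_fluxes(self):
        assert water_balance_step(100.0, 0, 0, 0) == (100.0, 0.0)

    def test_arithmetic(self):
        sw, ea = water_balance_step(100.0, precip=10.0, irrigation=20.0, ea=5.0, seep=3.0)
        assert sw == pytest.approx(122.0)
        assert ea == 5.0

    def test_excess_demand_truncated_and_closed(self):
        sw, ea = water_balance_step(4.0, precip=0, irrigation=0, ea=10.0)
        assert sw == 0.0
        assert ea == pytest.approx(4.0)
        assert 4.0 + 0 - ea - sw == pytest.approx(0.0)

    def test_negative_flux_rejected(self):
        with pytest.raises(ValidationError):
            water_balance_step(10.0, precip=-1.0, irrigation=0, ea=0)

    def test_non_et_losses_beyond_store_fail(self):
        with pytest.raises(NumericalError):
            water_balance_step(1.0, precip=0, irrigation=0, ea=0, seep=5.0)


class TestPercolate:
    def test_at_field_capacity_no_seepage(self):
        prof = two_layer_profile()
        sw = [ly.fc * prof.thickness(i) for i, ly in enumerate(prof.layers)]
        new, seep = percolate(prof, sw)
        assert seep == 0.0
        assert new == pytest.approx(sw)

    def test_huge_ksat_drains_nearly_all_excess(self):
        ly = SoilLayer(depth_bottom=300, bulk_density=1.4, awc=0.15, ksat=500.0,
                       clay=10.0, silt=40.0, sand=50.0)
        prof = build_profile("fast", [ly])
        fc_mm = prof.layers[0].fc * 300.0
        new, seep = percolate(prof, [fc_mm + 50.0])
        assert seep > 49.0
        assert new[0] == pytest.approx(fc_mm + 50.0 - seep)

    def test_two_layer_hand_case(self):
        prof = two_layer_profile()
        fc0 = prof.layers[0].fc * 200.0
        fc1 = prof.layers[1].fc * 400.0
        sat0 = prof.layers[0].porosity * 200.0
        sat1 = prof.layers[1].porosity * 400.0
        sw = [fc0 + 30.0, fc1]
        # manual: layer 1 drains 30·(1−exp(−24/TT1)); layer 2 receives it,
        # then drains its own excess at TT2
        tt1 = (sat0 - fc0) / 12.0
        drain1 = 30.0 * (1.0 - math.exp(-24.0 / tt1))
        tt2 = (sat1 - fc1) / 6.0
        drain2 = drain1 * (1.0 - math.exp(-24.0 / tt2))
        new, seep = percolate(prof, sw)
        assert new[0] == pytest.approx(fc0 + 30.0 - drain1)
        assert new[1] == pytest.approx(fc1 + drain1 - drain2)
        assert seep == pytest.approx(drain2)

    def test_saturation_overflow_cascades(self):
        prof = two_layer_profile()
        sat0 = prof.layers[0].porosity * 200.0
        new, seep = percolate(prof, [sat0 + 80.0, prof.layers[1].fc * 400.0])
        assert new[0] <= sat0
        assert new[1] + seep > 80.0 * 0.9  # overflow moved down, not lost
        total_before = sat0 + 80.0 + prof.layers[1].fc * 400.0
        assert math.fsum(new) + seep == pytest.approx(total_before)


class TestIrrigation:
    def test_maize_june_13_quota(self, tables):
        sched = tables["schedules"]["Summer maize"]
        assert irrigation_depth(sched, dt.date(2003, 6, 13)) == pytest.approx(105.0)

    def test_non_event_date_no_change(self, tables):
        sched = tables["schedules"]["Summer maize"]
        prof = tables["soils"]["Irrigated desert soil"]
        state = initial_state(prof)
        before = list(state.sw_by_layer)
        assert apply_irrigation(sched, dt.date(2003, 6, 14), state) == 0.0
        assert state.sw_by_layer == before

    def test_watermelon_annual_total_is_quota_sum(self, tables):
        sched = tables["schedules"]["Watermelon"]
        year_total = math.fsum(
            irrigation_depth(sched, dt.date(2003, 1, 1) + dt.timedelta(days=i))
            for i in range(365)
        )
        assert year_total == pytest.approx(math.fsum(e.depth for e in sched))
        assert year_total == pytest.approx(375.0)


class TestSimulateHru:
    def test_no_supply_no_et(self, tables, weather_3y):
        dry_weather = [
            type(d)(**{**d.__dict__, "precip": 0.0})
            for d in weather_3y
            if d.date.year == weather_3y[0].date.year
        ]
        hru = HRU(id="dry", area=1.0, soil=tables["soils"]["Irrigated desert soil"],
                  crop=tables["crops"]["Summer maize"], schedule=())
        res = simulate_hru(hru, dry_weather, tables["params"], initial="wp", spinup=0)
        annual = res.annual()
        assert float(annual["transp"].sum()) == pytest.approx(0.0, abs=1e-9)
        # only the thin surface-layer store above 0.5·WP can evaporate
        assert float(annual["et_act"].sum()) < 25.0

    def test_deterministic_given_inputs(self, tables, weather_3y, maize_hru):
        r1 = simulate_hru(maize_hru, weather_3y, tables["params"])
        r2 = simulate_hru(maize_hru, weather_3y, tables["params"])
        assert r1.daily.equals(r2.daily)

    def test_actual_et_never_exceeds_potential(self, tables, weather_3y, maize_hru):
        for module in ("original", "dualkc"):
            res = simulate_hru(maize_hru, weather_3y, tables["params"], module=module)
            daily = res.daily
            # demand-side bound plus any same-day canopy carry-over
            assert (daily["et_act"] <= daily["etc_demand"] + daily["ecan"] + 1e-9).all()

    def test_dualkc_daily_etc_below_kcmax_et0(self, tables, weather_3y, maize_hru):
        res = simulate_hru(maize_hru, weather_3y, tables["params"], module="dualkc")
        daily = res.daily
        kcmax_bound = 1.35  # kcmax under the clamped climate inputs never exceeds this
        assert (daily["et_act"] <= kcmax_bound * daily["et0"] + daily["ecan"] + 1e-9).all()

    def test_five_day_trace_matches_manual_composition(self, tables, weather_3y, maize_hru):
        """Step-by-step recomposition of the daily loop, dual-Kc mode."""
        from aridet import kr_modified, kc_max, adjust_kcb, kcb_curve
        from aridet import phenology as ph
        from aridet.et_dualkc import surface_state
        from aridet.et_swat import canopy_capacity, plant_uptake_by_layer
        from aridet.reference_et import et0_penman_monteith

        params = tables["params"]
        start = dt.date(weather_3y[0].date.year, 6, 10)
        window = [d for d in weather_3y if start <= d.date < start + dt.timedelta(days=5)]
        res = simulate_hru(maize_hru, window, params, spinup=0)

        prof = maize_hru.soil
        crop = maize_hru.crop
        sw = [ly.fc * prof.thickness(i) for i, ly in enumerate(prof.layers)]
        canopy = 0.0
        de = 0.0
        for i, day in enumerate(window):
            dos = ph.day_of_season(crop, day.date)
            lai = ph.lai(crop, dos)
            h = ph.height(crop, dos)
            cap = canopy_capacity(params.canmx, lai, crop.lai_max)
            drip = max(canopy - cap, 0.0)
            canopy -= drip
            caught = min(day.precip, cap - canopy)
            canopy += caught
            wetting = day.precip - caught + drip
            irr = 105.0 if (day.date.month, day.date.day) == (6, 13) else 0.0
            sw[0] += wetting + irr
            et0 = et0_penman_monteith(day)
            surf = surface_state(prof, sw[0], de)
            kcb = adjust_kcb(kcb_curve(crop, dos), day.wind_u2, day.rh_min, h)
            kcmax = kc_max(kcb, day.wind_u2, day.rh_min, h)
            kr = kr_modified(surf.fc_mm, surf.st_surface, surf.wp_mm)
            ke_val = max(kr * (kcmax - kcb), 0.0)
            evap_demand = ke_val * et0
            ecan = min(canopy, evap_demand)
            canopy -= ecan
            evap = min(evap_demand - ecan, max(surf.st_surface - 0.5 * surf.wp_mm, 0.0))
            sw[0] -= evap
            uptake = plant_uptake_by_layer(
                kcb * et0, prof, ph.root_depth(crop, dos), params.epco, sw
            )
            for j, u in enumerate(uptake):
                sw[j] -= u
            sw, seep = percolate(prof, sw)
            row = res.daily.iloc[i]
            assert row["et0"] == pytest.approx(et0, abs=1e-12)
            assert row["et_act"] == pytest.approx(ecan + evap + math.fsum(uptake), abs=1e-9)
            assert row["seep"] == pytest.approx(seep, abs=1e-9)
            assert row["sw_total"] == pytest.approx(math.fsum(sw), abs=1e-9)

    def test_closure_tracked_below_tolerance(self, tables, weather_3y, maize_hru):
        for module in ("original", "dualkc"):
            res = simulate_hru(maize_hru, weather_3y, tables["params"], module=module)
            assert res.max_closure_error < 1e-6


class TestScenarioAggregation:
    def test_identical_crop_et_is_invariant(self, tables):
        et = {c: 500.0 for c in tables["scenarios"]["current"].proportions}
        for scen in tables["scenarios"].values():
            assert apply_scenario(scen, et) == pytest.approx(500.0)

    def test_weighted_mean_toy_case(self):
        scen = Scenario(name="toy", proportions={"a": 0.25, "b": 0.75})
        assert apply_scenario(scen, {"a": 10.0, "b": 20.0}) == pytest.approx(17.5)

    def test_unknown_crop_rejected(self):
        scen = Scenario(name="toy", proportions={"a": 1.0})
        with pytest.raises(ValidationError, match="unknown crop"):
            apply_scenario(scen, {"b": 10.0})

    def test_identity_scenario_equals_current(self, tables, weather_3y):
        hrus = build_district_hrus(
            tables["soils"], tables["crops"], tables["schedules"]
        )
        scens = tables["scenarios"]
        dres = simulate_district(hrus, weather_3y, tables["params"], scens)
        current = dres.scenario_mean_et["current"]
        by_hand = apply_scenario(scens["current"], dres.crop_mean_et)
        assert current == pytest.approx(by_hand, abs=1e-9)


class TestSimulateDistrict:
    def test_single_hru_district_equals_hru_run(self, tables, weather_3y, maize_hru):
        scen = Scenario(name="only-maize", proportions={"Summer maize": 1.0})
        dres = simulate_district(
            [maize_hru], weather_3y, tables["params"], {"s": scen},
            soil_shares={"Irrigated desert soil": 1.0},
        )
        solo = simulate_hru(maize_hru, weather_3y, tables["params"])
        assert dres.scenario_mean_et["s"] == pytest.approx(solo.mean_annual_et)

    def test_replacing_high_kcb_crop_lowers_et(self, tables, weather_3y):
        crops = tables["crops"]
        hrus = build_district_hrus(tables["soils"], crops, tables["schedules"])
        # highest-Kcb crop: spring wheat (1.27); lowest: watermelon (1.05)
        all_wheat = Scenario("wheat", {"Spring wheat": 1.0})
        all_melon = Scenario("melon", {"Watermelon": 1.0})
        dres = simulate_district(
            hrus, weather_3y, tables["params"], {"w": all_wheat, "m": all_melon}
        )
        assert dres.scenario_mean_et["m"] < dres.scenario_mean_et["w"]

    def test_scenario_order_independence(self, tables, weather_3y):
        hrus = build_district_hrus(tables["soils"], tables["crops"], tables["schedules"])
        scens = tables["scenarios"]
        fwd = simulate_district(hrus, weather_3y, tables["params"], scens)
        rev = simulate_district(
            hrus, weather_3y, tables["params"], dict(reversed(list(scens.items())))
        )
        for k in scens:
            assert fwd.scenario_mean_et[k] == pytest.approx(rev.scenario_mean_et[k])
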