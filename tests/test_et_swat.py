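"""Original SWAT-style ET partition: canopy, transpiration gate, soil depth
distribution and the smaller-value selection rule."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from aridet import (
    CanopyState,
    ModelParams,
    SoilLayer,
    ValidationError,
    actual_et_original,
    build_profile,
    canopy_evaporation,
    max_transpiration,
    soil_evap_by_layer,
    soil_evap_depth_fraction,
)
from aridet.et_swat import original_et_step, plant_uptake_by_layer


def one_layer_profile(depth=100.0, awc=0.17, clay=15.0):
    ly = SoilLayer(depth_bottom=depth, bulk_density=1.4, awc=awc, ksat=10.0,
                   clay=clay, silt=45.0, sand=100.0 - 45.0 - clay)
    return build_profile("loam", [ly])


class TestCanopyEvaporation:
    def test_demand_below_storage(self):
        ecan, e0p, new = canopy_evaporation(1.0, CanopyState(2.0, 3.0))
        assert (ecan, e0p) == (1.0, 0.0)
        assert new.storage == pytest.approx(1.0)

    def test_demand_exhausts_storage(self):
        ecan, e0p, new = canopy_evaporation(5.0, CanopyState(2.0, 3.0))
        assert (ecan, e0p) == (2.0, 3.0)
        assert new.storage == 0.0

    def test_zero_demand_leaves_storage(self):
        ecan, e0p, new = canopy_evaporation(0.0, CanopyState(2.0, 3.0))
        assert (ecan, e0p) == (0.0, 0.0)
        assert new.storage == 2.0

    def test_negative_demand_rejected(self):
        with pytest.raises(ValidationError):
            canopy_evaporation(-0.1, CanopyState(0.0, 1.0))


class TestMaxTranspiration:
    @pytest.mark.parametrize(
        "lai,e0p,expected",
        [(0.0, 4.0, 0.0), (3.0, 4.0, 4.0), (1.5, 4.0, 2.0), (5.0, 4.0, 4.0)],
    )
    def test_lai_gate(self, lai, e0p, expected):
        assert max_transpiration(e0p, lai) == pytest.approx(expected)

    def test_continuous_at_lai_3(self):
        below = max_transpiration(4.0, 3.0 - 1e-12)
        above = max_transpiration(4.0, 3.0 + 1e-12)
        assert below == pytest.approx(above, abs=1e-9)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValidationError):
            max_transpiration(1.0, -0.5)


class TestDepthFraction:
    def test_zero_at_surface(self):
        assert soil_evap_depth_fraction(0.0) == 0.0

    def test_half_from_top_10mm(self):
        assert round(soil_evap_depth_fraction(10.0), 2) == 0.50

    def test_95pct_from_top_100mm(self):
        assert round(soil_evap_depth_fraction(100.0), 2) == 0.95

    @given(st.floats(min_value=0.0, max_value=2000.0), st.floats(min_value=0.01, max_value=500.0))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_and_bounded(self, z, dz):
        # profile depths in use never exceed ~2 m, where the curve is
        # still strictly below 1 in double precision
        f1 = soil_evap_depth_fraction(z)
        f2 = soil_evap_depth_fraction(z + dz)
        assert 0.0 <= f1 < 1.0
        assert f2 > f1


class TestSoilEvapByLayer:
    def test_single_layer_esco_one(self):
        prof = one_layer_profile(depth=100.0)
        demand = soil_evap_by_layer(10.0, prof, esco=1.0)
        assert demand[0] == pytest.approx(10.0 * soil_evap_depth_fraction(100.0))
        assert demand[0] == pytest.approx(9.5, abs=0.05)

    def test_esco_zero_gives_maximum_compensation(self):
        prof = one_layer_profile(depth=100.0)
        demand = soil_evap_by_layer(10.0, prof, esco=0.0)
        assert demand[0] == pytest.approx(10.0 * soil_evap_depth_fraction(100.0))

    def test_total_never_exceeds_es_max(self):
        layers = [
            SoilLayer(depth_bottom=d, bulk_density=1.4, awc=0.1, ksat=10.0,
                      clay=10.0, silt=40.0, sand=50.0)
            for d in (50, 150, 400, 1000)
        ]
        prof = build_profile("stack", layers)
        for esco in (0.0, 0.5, 0.875, 1.0):
            total = math.fsum(soil_evap_by_layer(7.3, prof, esco))
            assert total <= 7.3 + 1e-12

    def test_supply_limited_by_half_wilting_point(self):
        prof = one_layer_profile(depth=100.0)
        wp_mm = prof.layers[0].wp * 100.0
        dry = [0.6 * wp_mm]
        demand = soil_evap_by_layer(10.0, prof, esco=1.0, sw_by_layer=dry)
        assert demand[0] == pytest.approx(0.1 * wp_mm)

    def test_zero_demand(self):
        prof = one_layer_profile()
        assert soil_evap_by_layer(0.0, prof, esco=0.5) == [0.0]


class TestPlantUptake:
    def test_never_extracts_below_wilting_point(self):
        prof = one_layer_profile(depth=500.0)
        wp_mm = prof.layers[0].wp * 500.0
        sw = [wp_mm + 2.0]
        take = plant_uptake_by_layer(10.0, prof, 500.0, epco=1.0, sw_by_layer=sw)
        assert take[0] == pytest.approx(2.0)

    def test_epco_enables_deep_compensation(self):
        layers = [
            SoilLayer(depth_bottom=d, bulk_density=1.4, awc=0.15, ksat=10.0,
                      clay=15.0, silt=40.0, sand=45.0)
            for d in (250, 500)
        ]
        prof = build_profile("two", layers)
        wp_mm = prof.layers[0].wp * 250.0
        fc_mm = prof.layers[0].fc * 250.0
        sw = [wp_mm, fc_mm]  # top dry, bottom wet
        none = math.fsum(plant_uptake_by_layer(5.0, prof, 500.0, 0.0, sw))
        full = math.fsum(plant_uptake_by_layer(5.0, prof, 500.0, 1.0, sw))
        assert full > none


class TestActualEt:
    def test_unconstrained_sum(self):
        assert actual_et_original(0.5, 3.0, 99.0, 2.0, 99.0) == pytest.approx(5.5)

    def test_bone_dry_soil_leaves_only_canopy(self):
        assert actual_et_original(0.5, 3.0, 0.0, 2.0, 0.0) == pytest.approx(0.5)

    def test_one_layer_step_matches_manual_trace(self):
        """Pencil-and-paper oracle for a single day on one 100-mm layer."""
        prof = one_layer_profile(depth=100.0)
        params = ModelParams(esco=1.0, epco=1.0)
        fc_mm = prof.layers[0].fc * 100.0
        sw = [fc_mm]
        e0, lai = 6.0, 1.5
        res, transp_ly, esoil_ly, _ = original_et_step(
            e0, lai, 100.0, CanopyState(1.0, 2.0), prof, sw, params
        )
        # manual: ecan = 1, e0' = 5; Et = 5*1.5/3 = 2.5 (ample water)
        assert res.ecan == pytest.approx(1.0)
        assert res.e0_prime == pytest.approx(5.0)
        assert res.et_max == pytest.approx(2.5)
        assert res.transp == pytest.approx(2.5)
        # soil demand: 5*exp(-0.75) cross-limited, then distributed to 100 mm
        es_pot = 5.0 * math.exp(-0.75)
        es_pot = min(es_pot, es_pot * 5.0 / (es_pot + 2.5))
        es_pot = min(es_pot, 5.0 - 2.5)
        want_esoil = es_pot * soil_evap_depth_fraction(100.0)
        assert res.esoil == pytest.approx(want_esoil)
        assert res.ea == pytest.approx(1.0 + 2.5 + want_esoil)
        assert res.ea <= e0 + 1.0

    def test_actual_never_exceeds_potential_plus_canopy(self):
        prof = one_layer_profile(depth=100.0)
        params = ModelParams()
        for lai in (0.0, 1.0, 3.0, 5.0):
            for storage in (0.0, 2.0):
                sw = [prof.layers[0].fc * 100.0]
                res, *_ = original_et_step(
                    5.0, lai, 100.0, CanopyState(storage, 3.0), prof, sw, params
                )
                assert res.ea <= 5.0 + storage + 1e-12
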