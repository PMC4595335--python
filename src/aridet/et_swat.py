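"""Original SWAT-style evapotranspiration partition.

Potential ET is split into evaporation of canopy-intercepted water, an
LAI-gated maximum transpiration, and depth-distributed soil evaporation;
the actual ET is the smaller of demand and the water each store can
supply ("the relatively smaller value" rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import ModelParams, SoilProfile, ValidationError

# Depth-distribution constant. The standard value 2.374 reproduces the
# module's defining anchors (50% of soil evaporation from 0–10 mm, 95%
# from 0–100 mm); an alternative printed variant 2.347 is accepted for
# comparison runs.
DEPTH_CONST_STANDARD = 2.374
DEPTH_CONST_VARIANT = 2.347


@dataclass
class CanopyState:
    """Free water held on the canopy (mm) and its current capacity."""

    storage: float = 0.0
    capacity: float = 0.0

    def __post_init__(self) -> None:
        if self.storage < -1e-12 or self.storage > self.capacity + 1e-9:
            raise ValidationError(
                f"canopy storage {self.storage} outside [0, capacity={self.capacity}]"
            )


@dataclass(frozen=True)
class OriginalEtResult:
    """Daily ET components of the original module (all mm)."""

    e0: float
    ecan: float
    e0_prime: float
    et_max: float
    transp: float
    esoil_by_layer: tuple[float, ...]
    ea: float

    @property
    def esoil(self) -> float:
        return math.fsum(self.esoil_by_layer)


def canopy_capacity(canmx: float, lai_now: float, lai_max: float) -> float:
    """Interception capacity (mm): canmx scaled by the LAI fraction."""
    if lai_max <= 0:
        return 0.0
    return canmx * min(lai_now / lai_max, 1.0)


def intercept_rainfall(precip: float, state: CanopyState) -> tuple[float, CanopyState]:
    """Fill canopy storage from rainfall; return (throughfall, new state)."""
    room = max(state.capacity - state.storage, 0.0)
    caught = min(precip, room)
    return precip - caught, CanopyState(storage=state.storage + caught, capacity=state.capacity)


def canopy_evaporation(e0: float, state: CanopyState) -> tuple[float, float, CanopyState]:
    """Evaporate intercepted water first.

    Returns (ecan, e0_prime, new state): if demand e0 does not exceed the
    stored water the whole demand is met from the canopy; otherwise the
    store is exhausted and the residual demand e0' passes to crop and soil.
    """
    if e0 < 0:
        raise ValidationError(f"negative potential evapotranspiration {e0}")
    if e0 <= state.storage:
        new = CanopyState(storage=state.storage - e0, capacity=state.capacity)
        return e0, 0.0, new
    ecan = state.storage
    new = CanopyState(storage=0.0, capacity=state.capacity)
    return ecan, e0 - ecan, new


def max_transpiration(e0_prime: float, lai: float) -> float:
    """LAI-gated maximum transpiration: e0'·LAI/3 up to LAI 3, then e0'."""
    if lai < 0:
        raise ValidationError(f"negative LAI {lai}")
    if e0_prime < 0:
        raise ValidationError(f"negative e0_prime {e0_prime}")
    if lai <= 3.0:
        return e0_prime * lai / 3.0
    return e0_prime


def soil_evap_depth_fraction(z: float, const: float = DEPTH_CONST_STANDARD) -> float:
    """Cumulative fraction of soil evaporation supplied above depth z (mm)."""
    if z <= 0.0:
        return 0.0
    return z / (z + math.exp(const - 0.00713 * z))


def soil_evap_by_layer(
    es_max: float,
    profile: SoilProfile,
    esco: float,
    sw_by_layer: list[float] | None = None,
    const: float = DEPTH_CONST_STANDARD,
) -> list[float]:
    """Distribute soil-evaporation demand over layers with ESCO compensation.

    Per-layer demand is ``es_max·(frac(z_bottom) − esco·frac(z_top))``
    clamped at zero — lowering ESCO lets deeper layers compensate for dry
    surface layers. The running total is capped at ``es_max``, and when
    soil-water states are supplied each layer's extraction is limited to
    its water above half the wilting-point equivalent.
    """
    if es_max < 0:
        raise ValidationError(f"negative es_max {es_max}")
    if not 0.0 <= esco <= 1.0:
        raise ValidationError(f"esco {esco} outside [0, 1]")
    tops = profile.layer_tops
    out: list[float] = []
    taken = 0.0
    for i, ly in enumerate(profile.layers):
        demand = es_max * (
            soil_evap_depth_fraction(ly.depth_bottom, const)
            - esco * soil_evap_depth_fraction(tops[i], const)
        )
        demand = max(demand, 0.0)
        demand = min(demand, es_max - taken)
        if sw_by_layer is not None:
            wp_mm = ly.wp * profile.thickness(i)
            supply = max(sw_by_layer[i] - 0.5 * wp_mm, 0.0)
            demand = min(demand, supply)
        out.append(demand)
        taken += demand
    return out


def plant_uptake_by_layer(
    et_max: float,
    profile: SoilProfile,
    root_depth: float,
    epco: float,
    sw_by_layer: list[float],
) -> list[float]:
    """Distribute transpiration demand over the root zone (SWAT form).

    Potential uptake follows the exponential depth distribution
    ``w(z) ∝ 1 − exp(−10·z/z_root)``; demand unmet in upper layers may be
    drawn from deeper layers in proportion to EPCO. Extraction from a
    layer never takes it below its wilting point.
    """
    if et_max <= 0 or root_depth <= 0:
        return [0.0] * len(profile.layers)
    norm = 1.0 - math.exp(-10.0)
    tops = profile.layer_tops

    def cum(z: float) -> float:
        z = min(z, root_depth)
        return et_max * (1.0 - math.exp(-10.0 * z / root_depth)) / norm

    out: list[float] = []
    deficit = 0.0
    for i, ly in enumerate(profile.layers):
        if tops[i] >= root_depth:
            out.append(0.0)
            continue
        demand = cum(ly.depth_bottom) - cum(tops[i]) + epco * deficit
        wp_mm = ly.wp * profile.thickness(i)
        supply = max(sw_by_layer[i] - wp_mm, 0.0)
        take = min(demand, supply)
        deficit = max(demand - take, 0.0) if epco > 0 else 0.0
        out.append(take)
    return out


def actual_et_original(
    ecan: float, et_max: float, plant_supply: float, esoil_demand: float, soil_supply: float
) -> float:
    """Actual ET: canopy term plus supply-limited transpiration and soil evaporation."""
    return ecan + min(et_max, plant_supply) + min(esoil_demand, soil_supply)


def original_et_step(
    e0: float,
    lai: float,
    root_depth: float,
    canopy: CanopyState,
    profile: SoilProfile,
    sw_by_layer: list[float],
    params: ModelParams,
    const: float = DEPTH_CONST_STANDARD,
) -> tuple[OriginalEtResult, list[float], list[float], CanopyState]:
    """One day of the original module.

    Returns (result, transp_by_layer, esoil_by_layer, new canopy state).
    Potential soil evaporation is the canopy-shaded residual
    ``e0'·exp(−0.5·LAI)``, reduced by the standard SWAT cross-limitation so
    transpiration and soil evaporation cannot jointly exceed e0'.
    """
    ecan, e0_prime, canopy = canopy_evaporation(e0, canopy)
    et_max = max_transpiration(e0_prime, lai)
    es_pot = e0_prime * math.exp(-0.5 * lai)
    if es_pot + et_max > 0:
        es_pot = min(es_pot, es_pot * e0_prime / (es_pot + et_max))
    transp_by_layer = plant_uptake_by_layer(
        et_max, profile, root_depth, params.epco, sw_by_layer
    )
    transp = math.fsum(transp_by_layer)
    # the "smaller value" rule: joint demand never exceeds the residual
    # potential, so actual ET stays below e0 plus stored canopy water
    es_pot = min(es_pot, max(e0_prime - transp, 0.0))
    esoil_by_layer = soil_evap_by_layer(
        es_pot, profile, params.esco, sw_by_layer, const=const
    )
    esoil = math.fsum(esoil_by_layer)
    ea = ecan + transp + esoil
    result = OriginalEtResult(
        e0=e0,
        ecan=ecan,
        e0_prime=e0_prime,
        et_max=et_max,
        transp=transp,
        esoil_by_layer=tuple(esoil_by_layer),
        ea=ea,
    )
    return result, transp_by_layer, esoil_by_layer, canopy
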