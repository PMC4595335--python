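"""FAO-56 dual crop coefficient ET with a modified soil-evaporation
reduction coefficient.

Crop ET is ``ETc = (Kcb + Ke)·ET0``: a basal (transpiration) coefficient
interpolated from tabulated stage values and adjusted for wind, humidity
and crop height, plus a soil-evaporation coefficient ``Ke = Kr·(Kcmax −
Kcb)``. Two forms of the drying-reduction coefficient Kr are available:

* ``fao`` — the classic two-stage depletion form driven by cumulative
  surface-layer evaporation (REW/TEW thresholds);
* ``modified`` (default) — a surface-soil-water-content form,
  ``Kr = (FC − St)/(FC − 0.5·WP)`` in mm over the evaporation layer, which
  needs only the simulated surface water state. Note this form *increases*
  evaporation as the surface dries below field capacity and gives Kr = 0
  at field capacity — the inverse of the FAO stage-1 behaviour; it is
  implemented exactly as defined, and the FAO form remains switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .types import CropParams, ValidationError


class AdjustedKcb(float):
    """A climate-adjusted Kcb. The type guards against double adjustment."""


@dataclass
class DualKcState:
    """Surface-layer evaporation bookkeeping (all mm over the Ze layer)."""

    de: float          # cumulative evaporation depletion (FAO two-stage form)
    tew: float         # total evaporable water
    rew: float         # readily evaporable water
    st_surface: float  # current surface-layer water
    fc_mm: float
    wp_mm: float

    def __post_init__(self) -> None:
        if not self.rew < self.tew:
            raise ValidationError(f"require rew < tew, got rew={self.rew}, tew={self.tew}")
        if not -1e-9 <= self.de <= self.tew + 1e-9:
            raise ValidationError(f"de={self.de} outside [0, tew={self.tew}]")


@dataclass(frozen=True)
class DualKcResult:
    """Daily dual-Kc coefficients and the resulting unstressed ET demands."""

    kcb: float
    ke: float
    kcmax: float
    kr: float
    etc: float
    transp: float
    evap: float


def surface_state(profile, sw_top: float, de: float = 0.0) -> DualKcState:
    """Build the Ze-layer state from the top soil layer's water content.

    The surface store St is the top layer's water rescaled to the
    evaporation-layer thickness Ze; TEW = (FC − 0.5·WP)·Ze and REW is
    0.45·TEW bounded to [2, 10] mm (FAO-representative for the textures
    involved).
    """
    top = profile.layers[0]
    thickness = profile.thickness(0)
    scale = profile.ze / thickness
    fc_mm = top.fc * profile.ze
    wp_mm = top.wp * profile.ze
    tew = fc_mm - 0.5 * wp_mm
    rew = min(max(0.45 * tew, 2.0), 10.0)
    if rew >= tew:
        rew = 0.5 * tew
    return DualKcState(
        de=min(max(de, 0.0), tew),
        tew=tew,
        rew=rew,
        st_surface=sw_top * scale,
        fc_mm=fc_mm,
        wp_mm=wp_mm,
    )


def kcb_curve(crop: CropParams, day_of_season: int | None) -> float:
    """Tabulated Kcb on a given day: the four-segment FAO-56 seasonal curve.

    Out-of-season days return 0 (bare soil).
    """
    if day_of_season is None or not 0 <= day_of_season < crop.season_length:
        return 0.0
    d = day_of_season
    if d < crop.l_ini:
        return crop.kcb_ini
    d -= crop.l_ini
    if d < crop.l_dev:
        return crop.kcb_ini + (crop.kcb_mid - crop.kcb_ini) * (d + 1) / crop.l_dev
    d -= crop.l_dev
    if d < crop.l_mid:
        return crop.kcb_mid
    d -= crop.l_mid
    return crop.kcb_mid + (crop.kcb_end - crop.kcb_mid) * (d + 1) / crop.l_late


def _climate_term(u2: float, rh_min: float, h: float) -> float:
    u2c = min(max(u2, 1.0), 6.0)
    rhc = min(max(rh_min, 20.0), 80.0)
    return (0.04 * (u2c - 2.0) - 0.004 * (rhc - 45.0)) * (h / 3.0) ** 0.3


def adjust_kcb(kcb_tab: float, u2: float, rh_min: float, h: float) -> AdjustedKcb:
    """Climate-adjust a tabulated Kcb for wind, dryness and crop height.

    u2 is clamped to [1, 6] m/s and RHmin to [20, 80]% before use. Passing
    an already-adjusted value is rejected (the correction is not idempotent).
    """
    if isinstance(kcb_tab, AdjustedKcb):
        raise ValidationError("kcb value is already climate-adjusted")
    if h <= 0:
        raise ValidationError(f"crop height {h} must be positive")
    return AdjustedKcb(max(kcb_tab + _climate_term(u2, rh_min, h), 0.0))


def kc_max(kcb: float, u2: float, rh_min: float, h: float) -> float:
    """Upper bound of Kc after wetting: max(1.2 + climate term, Kcb + 0.05)."""
    if h <= 0:
        raise ValidationError(f"crop height {h} must be positive")
    return max(1.2 + _climate_term(u2, rh_min, h), float(kcb) + 0.05)


def kr_two_stage(state: DualKcState) -> float:
    """FAO two-stage drying: Kr = 1 until REW is depleted, then linear to 0 at TEW."""
    if state.tew <= state.rew:
        raise ValidationError(f"tew ({state.tew}) must exceed rew ({state.rew})")
    if state.de <= state.rew:
        return 1.0
    return min(max((state.tew - state.de) / (state.tew - state.rew), 0.0), 1.0)


def kr_modified(fc_mm: float, st_mm: float, wp_mm: float) -> float:
    """Soil-water-content form of the evaporation reduction coefficient.

    Kr = (FC − St)/(FC − 0.5·WP), clamped to [0, 1], all in mm over the
    surface evaporation layer.
    """
    denom = fc_mm - 0.5 * wp_mm
    if denom <= 0:
        raise ValidationError(
            f"degenerate denominator: fc={fc_mm} must exceed 0.5·wp={0.5 * wp_mm}"
        )
    return min(max((fc_mm - st_mm) / denom, 0.0), 1.0)


def ke(kr: float, kcmax: float, kcb: float) -> float:
    """Soil evaporation coefficient: Kr·(Kcmax − Kcb), floored at 0."""
    if not 0.0 <= kr <= 1.0:
        raise ValidationError(f"kr {kr} outside [0, 1]")
    return max(kr * (kcmax - float(kcb)), 0.0)


def etc_dual(kcb: float, ke_val: float, et0: float) -> tuple[float, float, float]:
    """Crop ET and its partition: (etc, transpiration, soil evaporation)."""
    if min(float(kcb), ke_val, et0) < 0:
        raise ValidationError("kcb, ke and et0 must be nonnegative")
    transp = float(kcb) * et0
    evap = ke_val * et0
    return transp + evap, transp, evap


def dualkc_step(
    et0: float,
    crop: CropParams,
    day_of_season: int | None,
    u2: float,
    rh_min: float,
    h: float,
    state: DualKcState,
    kr_method: str = "modified",
) -> DualKcResult:
    """Coefficients and unstressed ET demand for one day (no state update)."""
    kcb_tab = kcb_curve(crop, day_of_season)
    if kcb_tab > 0:
        kcb = adjust_kcb(kcb_tab, u2, rh_min, h)
    else:
        kcb = AdjustedKcb(0.0)
    kcmax = kc_max(kcb, u2, rh_min, h)
    if kr_method == "modified":
        kr = kr_modified(state.fc_mm, state.st_surface, state.wp_mm)
    elif kr_method == "fao":
        kr = kr_two_stage(state)
    else:
        raise ValidationError(f"unknown kr method {kr_method!r}; use 'modified' or 'fao'")
    ke_val = ke(kr, kcmax, kcb)
    etc, transp, evap = etc_dual(kcb, ke_val, et0)
    return DualKcResult(
        kcb=float(kcb), ke=ke_val, kcmax=kcmax, kr=kr, etc=etc, transp=transp, evap=evap
    )


def update_depletion(state: DualKcState, evap_actual: float, wetting: float) -> DualKcState:
    """Advance the FAO depletion bookkeeping after a day.

    Wetting (infiltrated rain + irrigation) refills the surface layer and
    reduces the depletion toward 0; actual evaporation deepens it. The
    result is clamped to [0, TEW].
    """
    de = min(max(state.de + evap_actual - wetting, 0.0), state.tew)
    return replace(state, de=de)
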