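"""Domain types for the irrigation-district evapotranspiration simulator.

All quantities use the units conventional in irrigation engineering:
water depths in mm, temperatures in °C, wind speed in m/s at 2 m height,
areas in hm² (hectares), money in yuan.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace


class ValidationError(ValueError):
    """Raised when an input violates a physical or structural invariant."""


class NumericalError(RuntimeError):
    """Raised when the simulation reaches a numerically inconsistent state."""


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological forcing at a station.

    ``solar`` (MJ m⁻² d⁻¹) may be None, in which case reference-ET routines
    estimate it from the diurnal temperature range. ``et0_obs`` carries a
    measured reference-ET value that bypasses computation when present.
    """

    date: dt.date
    precip: float
    tmax: float
    tmin: float
    rh_mean: float
    rh_min: float
    wind_u2: float
    solar: float | None = None
    et0_obs: float | None = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValidationError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if not (0.0 <= self.rh_min <= self.rh_mean <= 100.0):
            raise ValidationError(
                f"{self.date}: require 0 <= rh_min <= rh_mean <= 100, "
                f"got rh_min={self.rh_min}, rh_mean={self.rh_mean}"
            )
        if self.precip < 0:
            raise ValidationError(f"{self.date}: negative precipitation")
        if self.wind_u2 < 0:
            raise ValidationError(f"{self.date}: negative wind speed")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class Site:
    """Location constants for reference-ET calculations."""

    latitude_deg: float = 37.9   # Wuwei, Gansu
    elevation_m: float = 1550.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValidationError(f"latitude {self.latitude_deg} outside [-90, 90]")


@dataclass(frozen=True)
class SoilLayer:
    """One soil horizon: physical properties plus derived water constants.

    ``fc`` and ``wp`` are volumetric fractions; when not measured they are
    derived from texture by a pedotransfer rule with ``fc - wp`` pinned to
    the measured available water capacity (see ``core.derive_soil_water_constants``).
    """

    depth_bottom: float          # mm below surface
    bulk_density: float          # g/cm³
    awc: float                   # volumetric fraction
    ksat: float                  # mm/h
    clay: float
    silt: float
    sand: float
    fc: float | None = None
    wp: float | None = None
    # Published soil surveys occasionally print internally inconsistent
    # texture rows; set False to accept such a row as-is (the water
    # constants depend on clay content only, not the sum).
    texture_check: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.awc <= 0.5):
            raise ValidationError(f"awc {self.awc} outside (0, 0.5]")
        if self.ksat <= 0:
            raise ValidationError(f"ksat {self.ksat} must be positive")
        total = self.clay + self.silt + self.sand
        if self.texture_check and not (95.0 <= total <= 105.0):
            raise ValidationError(
                f"texture fractions sum to {total:.2f}%, outside [95, 105]"
            )
        if self.fc is not None and self.wp is not None:
            if self.wp >= self.fc:
                raise ValidationError(f"wp {self.wp} must be below fc {self.fc}")

    @property
    def porosity(self) -> float:
        """Total porosity from bulk density, particle density 2.65 g/cm³."""
        return 1.0 - self.bulk_density / 2.65


@dataclass(frozen=True)
class SoilProfile:
    """An ordered stack of soil layers with a surface evaporation layer.

    ``ze`` is the thickness (mm) of the notional surface layer from which
    stage-two soil evaporation is supplied (FAO-56 convention, default 100 mm).
    """

    name: str
    layers: tuple[SoilLayer, ...]
    ze: float = 100.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError(f"soil {self.name!r} has no layers")
        depths = [ly.depth_bottom for ly in self.layers]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValidationError(
                f"soil {self.name!r}: layer bottoms must strictly increase, got {depths}"
            )
        for ly in self.layers:
            if ly.fc is None or ly.wp is None:
                raise ValidationError(
                    f"soil {self.name!r}: layers must carry fc/wp "
                    "(use core.build_profile to derive them)"
                )
            if abs((ly.fc - ly.wp) - ly.awc) > 1e-6:
                raise ValidationError(
                    f"soil {self.name!r}: fc - wp = {ly.fc - ly.wp:.6f} "
                    f"does not reproduce awc = {ly.awc}"
                )

    @property
    def layer_tops(self) -> tuple[float, ...]:
        return (0.0,) + tuple(ly.depth_bottom for ly in self.layers[:-1])

    def thickness(self, i: int) -> float:
        return self.layers[i].depth_bottom - self.layer_tops[i]

    @property
    def total_depth(self) -> float:
        return self.layers[-1].depth_bottom


@dataclass(frozen=True)
class CropParams:
    """Phenology and crop coefficients for one crop.

    Basal crop coefficients are FAO-56 tabulated values for the initial,
    mid-season and end-of-season stages; the seasonal curve is the standard
    four-segment interpolation over the stage lengths.
    """

    name: str
    kcb_ini: float
    kcb_mid: float
    kcb_end: float
    plant_month: int
    plant_day: int
    l_ini: int
    l_dev: int
    l_mid: int
    l_late: int
    height_max: float        # m
    lai_max: float
    root_depth_max: float    # mm

    def __post_init__(self) -> None:
        for k in (self.kcb_ini, self.kcb_mid, self.kcb_end):
            if not (0.0 < k <= 1.5):
                raise ValidationError(f"{self.name}: kcb {k} outside (0, 1.5]")
        for length in (self.l_ini, self.l_dev, self.l_mid, self.l_late):
            if length <= 0:
                raise ValidationError(f"{self.name}: non-positive stage length")
        if self.height_max <= 0:
            raise ValidationError(f"{self.name}: height_max must be positive")

    @property
    def season_length(self) -> int:
        return self.l_ini + self.l_dev + self.l_mid + self.l_late

    def planting_date(self, year: int) -> dt.date:
        return dt.date(year, self.plant_month, self.plant_day)


@dataclass(frozen=True)
class IrrigationEvent:
    """A single scheduled application: day-of-year recurrence and depth (mm)."""

    month: int
    day: int
    depth: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError(f"irrigation depth {self.depth} must be positive")
        dt.date(2001, self.month, self.day)  # validates the calendar day

    def on(self, year: int) -> dt.date:
        return dt.date(year, self.month, self.day)


@dataclass(frozen=True)
class HRU:
    """A hydrological response unit: one (soil, crop, schedule) combination."""

    id: str
    area: float              # hm²
    soil: SoilProfile
    crop: CropParams
    schedule: tuple[IrrigationEvent, ...]
    subdivision_id: str = "1"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError(f"HRU {self.id}: area must be positive")


@dataclass(frozen=True)
class Scenario:
    """A district planting scenario: crop-name → fraction of cultivated area."""

    name: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.proportions.values()):
            raise ValidationError(f"scenario {self.name!r}: negative proportion")
        total = math.fsum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"scenario {self.name!r}: proportions sum to {total!r}, not 1"
            )


@dataclass(frozen=True)
class EconRecord:
    """Yield, price and unit input cost for one crop."""

    crop: str
    yield_kg_hm2: float
    price_yuan_kg: float
    unit_input_yuan_hm2: float

    def __post_init__(self) -> None:
        if min(self.yield_kg_hm2, self.price_yuan_kg, self.unit_input_yuan_hm2) < 0:
            raise ValidationError(f"{self.crop}: negative economics input")


_PARAM_RANGES = {
    "esco": (0.0, 1.0),
    "canmx": (0.0, 30.0),
    "gw_revap": (0.02, 0.2),
    "epco": (0.0, 1.0),
    "sol_awc_scale": (-0.5, 0.5),
}


@dataclass(frozen=True)
class ModelParams:
    """Calibratable simulation parameters.

    Defaults are the district calibration values. ``gw_revap`` is accepted
    for interface completeness but is inert: the simulator has no
    groundwater store, so it influences nothing.
    """

    esco: float = 0.875
    canmx: float = 9.853
    gw_revap: float = 0.115
    epco: float = 0.827
    sol_awc_scale: float = 0.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _PARAM_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")

    @staticmethod
    def ranges() -> dict[str, tuple[float, float]]:
        return dict(_PARAM_RANGES)

    def with_(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ET0Result:
    date: dt.date
    et0: float
    method: str

    def __post_init__(self) -> None:
        if self.et0 < 0:
            raise ValidationError(f"{self.date}: negative ET0")
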