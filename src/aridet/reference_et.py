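"""Daily reference evapotranspiration (ET0).

Three standard methods are provided — FAO-56 Penman–Monteith (the default
driver for the dual-crop-coefficient module), Priestley–Taylor and
Hargreaves — plus a pass-through for measured ET0 carried in the weather
file. All return mm/day for a well-watered clipped-grass reference surface.
"""

from __future__ import annotations

import math

from .types import Site, ValidationError, WeatherDay

STEFAN_BOLTZMANN = 4.903e-9       # MJ K⁻⁴ m⁻² d⁻¹
ALBEDO = 0.23
SOLAR_CONSTANT = 0.0820           # MJ m⁻² min⁻¹
KRS_INTERIOR = 0.16               # Hargreaves radiation coefficient, interior site
PT_ALPHA = 1.26


def saturation_vp(t: float) -> float:
    """Saturation vapour pressure (kPa) at temperature t (°C)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def svp_slope(t: float) -> float:
    """Slope of the saturation vapour-pressure curve (kPa/°C)."""
    return 4098.0 * saturation_vp(t) / (t + 237.3) ** 2


def psychrometric_constant(elevation_m: float) -> float:
    """γ (kPa/°C) from site elevation via the standard-atmosphere pressure."""
    p = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    return 0.000665 * p


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m⁻² d⁻¹)."""
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValidationError(f"latitude {latitude_deg} outside [-90, 90]")
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    return max(ra, 0.0)


def solar_radiation(day: WeatherDay, site: Site) -> float:
    """Measured Rs if present, else Hargreaves estimate from temperature range."""
    if day.solar is not None:
        return day.solar
    ra = extraterrestrial_radiation(site.latitude_deg, day.date.timetuple().tm_yday)
    return KRS_INTERIOR * math.sqrt(max(day.tmax - day.tmin, 0.0)) * ra


def net_radiation(day: WeatherDay, site: Site) -> float:
    """Daily net radiation Rn (MJ m⁻² d⁻¹) over the grass reference."""
    doy = day.date.timetuple().tm_yday
    ra = extraterrestrial_radiation(site.latitude_deg, doy)
    rs = solar_radiation(day, site)
    rso = (0.75 + 2e-5 * site.elevation_m) * ra
    rns = (1.0 - ALBEDO) * rs
    ea = actual_vp(day)
    tmax_k4 = (day.tmax + 273.16) ** 4
    tmin_k4 = (day.tmin + 273.16) ** 4
    rel = min(rs / rso, 1.0) if rso > 0 else 0.0
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


def actual_vp(day: WeatherDay) -> float:
    """Actual vapour pressure (kPa) from mean relative humidity."""
    es = 0.5 * (saturation_vp(day.tmax) + saturation_vp(day.tmin))
    return es * day.rh_mean / 100.0


def et0_penman_monteith(day: WeatherDay, site: Site = Site()) -> float:
    """FAO-56 Penman–Monteith daily reference ET (mm/day), G = 0."""
    t = day.tmean
    delta = svp_slope(t)
    gamma = psychrometric_constant(site.elevation_m)
    es = 0.5 * (saturation_vp(day.tmax) + saturation_vp(day.tmin))
    ea = actual_vp(day)
    rn = net_radiation(day, site)
    num = 0.408 * delta * rn + gamma * (900.0 / (t + 273.0)) * day.wind_u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * day.wind_u2)
    return max(num / den, 0.0)


def et0_hargreaves(day: WeatherDay, site: Site = Site()) -> float:
    """Hargreaves–Samani daily reference ET (mm/day)."""
    ra = extraterrestrial_radiation(site.latitude_deg, day.date.timetuple().tm_yday)
    trange = max(day.tmax - day.tmin, 0.0)
    return max(0.0023 * (day.tmean + 17.8) * math.sqrt(trange) * 0.408 * ra, 0.0)


def et0_priestley_taylor(day: WeatherDay, site: Site = Site(), alpha: float = PT_ALPHA) -> float:
    """Priestley–Taylor daily reference ET (mm/day): α × equilibrium evaporation."""
    delta = svp_slope(day.tmean)
    gamma = psychrometric_constant(site.elevation_m)
    rn = net_radiation(day, site)
    return max(alpha * delta / (delta + gamma) * 0.408 * rn, 0.0)


_METHODS = {
    "pm": et0_penman_monteith,
    "hargreaves": et0_hargreaves,
    "pt": et0_priestley_taylor,
}


def reference_et(day: WeatherDay, site: Site = Site(), method: str = "pm") -> float:
    """Dispatch on method name; ``observed`` uses the weather file's et0_obs."""
    if method == "observed":
        if day.et0_obs is None:
            raise ValidationError(f"{day.date}: method 'observed' but no et0_obs value")
        return day.et0_obs
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown ET0 method {method!r}; choose from {sorted(_METHODS)} or 'observed'"
        ) from None
    return fn(day, site)
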