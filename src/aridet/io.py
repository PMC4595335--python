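"""Table readers/writers and packaged district fixtures.

Weather, soils, crops, schedules, scenarios and economics all travel as
plain CSV. The packaged fixtures transcribe the district's published
tables (soil physical properties, irrigation scheduling, basal crop
coefficients, sensitivity parameter ranges, planting scenarios, crop
economics); the phenology table is a documented set of assumptions, since
planting dates and stage lengths were not published.
"""

from __future__ import annotations

import datetime as dt
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import (
    CropParams,
    EconRecord,
    IrrigationEvent,
    ModelParams,
    Scenario,
    SoilLayer,
    SoilProfile,
    ValidationError,
    WeatherDay,
)

WEATHER_COLUMNS = ["date", "precip", "tmax", "tmin", "rh_mean", "rh_min", "wind_u2"]
OPTIONAL_WEATHER_COLUMNS = ["solar", "et0_obs"]


class ConfigError(ValueError):
    """Raised for malformed configuration or missing table columns."""


# ---------------------------------------------------------------------------
# weather

def load_weather(path: str | Path) -> list[WeatherDay]:
    """Read a daily weather CSV into a validated list of :class:`WeatherDay`.

    Required columns: date, precip, tmax, tmin, rh_mean, rh_min, wind_u2.
    Optional: solar (MJ m⁻² d⁻¹), et0_obs (mm/d). Dates must be strictly
    increasing; gaps are tolerated but reported via a ``UserWarning``.
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing weather column(s) {missing}")
    days: list[WeatherDay] = []
    prev: dt.date | None = None
    gaps = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            day = WeatherDay(
                date=dt.date.fromisoformat(str(row.date)),
                precip=float(row.precip),
                tmax=float(row.tmax),
                tmin=float(row.tmin),
                rh_mean=float(row.rh_mean),
                rh_min=float(row.rh_min),
                wind_u2=float(row.wind_u2),
                solar=_opt(getattr(row, "solar", None)),
                et0_obs=_opt(getattr(row, "et0_obs", None)),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
        if prev is not None:
            if day.date <= prev:
                raise ValidationError(
                    f"{path} row {i + 2}: dates not strictly increasing "
                    f"({day.date} after {prev})"
                )
            gaps += (day.date - prev).days - 1
        prev = day.date
        days.append(day)
    if gaps:
        import warnings

        warnings.warn(f"{path}: weather series has {gaps} missing day(s)")
    return days


def write_weather(days: list[WeatherDay], path: str | Path) -> None:
    """Write a weather series as CSV (inverse of :func:`load_weather`)."""
    rows = []
    for d in days:
        rows.append(
            {
                "date": d.date.isoformat(),
                "precip": round(d.precip, 3),
                "tmax": round(d.tmax, 2),
                "tmin": round(d.tmin, 2),
                "rh_mean": round(d.rh_mean, 1),
                "rh_min": round(d.rh_min, 1),
                "wind_u2": round(d.wind_u2, 2),
            }
        )
    pd.DataFrame(rows, columns=WEATHER_COLUMNS).to_csv(path, index=False)


def _opt(v) -> float | None:
    if v is None or pd.isna(v):
        return None
    return float(v)


# ---------------------------------------------------------------------------
# pedotransfer

def derive_soil_water_constants(
    layer: SoilLayer, fc: float | None = None, wp: float | None = None
) -> tuple[float, float]:
    """Field capacity and wilting point (volumetric) for a soil layer.

    Explicit values pass through unchanged. Otherwise the wilting point is
    estimated from texture by a linear Saxton–Rawls-style rule,
    ``wp = 0.0263 + 0.00505 · clay%``, and the field capacity is pinned to
    ``wp + awc`` so that the measured available water capacity is honoured
    exactly (AWC is the authoritative measurement).
    """
    if fc is not None and wp is not None:
        return fc, wp
    if wp is None:
        wp = 0.0263 + 0.00505 * layer.clay
    if fc is None:
        fc = wp + layer.awc
    if wp <= 0:
        raise ValidationError(
            f"pedotransfer gives wp={wp:.4f} <= 0; supply fc/wp explicitly"
        )
    if fc >= layer.porosity:
        raise ValidationError(
            f"derived fc={fc:.4f} >= porosity {layer.porosity:.4f}; "
            "supply fc/wp explicitly"
        )
    return fc, wp


def build_profile(
    name: str,
    layers: list[SoilLayer],
    ze: float = 100.0,
    awc_scale: float = 0.0,
) -> SoilProfile:
    """Assemble a :class:`SoilProfile`, deriving fc/wp where absent.

    ``awc_scale`` applies the relative available-water-capacity adjustment
    used in calibration: awc → awc·(1 + awc_scale), fc re-pinned to wp + awc.
    """
    out = []
    for ly in layers:
        awc = ly.awc * (1.0 + awc_scale)
        ly = SoilLayer(
            depth_bottom=ly.depth_bottom,
            bulk_density=ly.bulk_density,
            awc=awc,
            ksat=ly.ksat,
            clay=ly.clay,
            silt=ly.silt,
            sand=ly.sand,
            fc=ly.fc,
            wp=ly.wp,
            texture_check=ly.texture_check,
        )
        fc, wp = derive_soil_water_constants(ly, ly.fc, ly.wp)
        if ly.fc is None or ly.wp is None:
            fc, wp = wp + awc, wp
        out.append(
            SoilLayer(
                depth_bottom=ly.depth_bottom,
                bulk_density=ly.bulk_density,
                awc=awc,
                ksat=ly.ksat,
                clay=ly.clay,
                silt=ly.silt,
                sand=ly.sand,
                fc=fc,
                wp=wp,
                texture_check=ly.texture_check,
            )
        )
    return SoilProfile(name=name, layers=tuple(out), ze=ze)


# ---------------------------------------------------------------------------
# fixture tables

def _data(fname: str) -> pd.DataFrame:
    with resources.files("aridet.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_soils(
    path: str | Path | None = None,
    awc_scale: float = 0.0,
    strict_texture: bool = False,
) -> dict[str, SoilProfile]:
    """Soil profiles keyed by soil-type name (packaged table by default).

    ``strict_texture`` enforces clay+silt+sand in [95, 105]%; the default is
    lenient because published survey tables occasionally contain rows whose
    printed fractions do not sum to 100 (one packaged sierozem layer does).
    """
    df = pd.read_csv(path) if path is not None else _data("soils.csv")
    profiles: dict[str, SoilProfile] = {}
    for soil, grp in df.groupby("soil", sort=False):
        layers = [
            SoilLayer(
                depth_bottom=float(r.depth_bottom_mm),
                bulk_density=float(r.bulk_density_g_cm3),
                awc=float(r.awc),
                ksat=float(r.ksat_mm_h),
                clay=float(r.clay_pct),
                silt=float(r.silt_pct),
                sand=float(r.sand_pct),
                texture_check=strict_texture,
            )
            for r in grp.itertuples(index=False)
        ]
        profiles[str(soil)] = build_profile(str(soil), layers, awc_scale=awc_scale)
    return profiles


def load_crops(
    kcb_path: str | Path | None = None, phenology_path: str | Path | None = None
) -> dict[str, CropParams]:
    """Crop parameters keyed by crop name: published Kcb + assumed phenology."""
    kcb = pd.read_csv(kcb_path) if kcb_path is not None else _data("kcb.csv")
    phen = (
        pd.read_csv(phenology_path, comment="#")
        if phenology_path is not None
        else _data("phenology.csv")
    )
    merged = kcb.merge(phen, on="crop", validate="one_to_one")
    crops: dict[str, CropParams] = {}
    for r in merged.itertuples(index=False):
        crops[str(r.crop)] = CropParams(
            name=str(r.crop),
            kcb_ini=float(r.kcb_ini),
            kcb_mid=float(r.kcb_mid),
            kcb_end=float(r.kcb_end),
            plant_month=int(r.plant_month),
            plant_day=int(r.plant_day),
            l_ini=int(r.l_ini),
            l_dev=int(r.l_dev),
            l_mid=int(r.l_mid),
            l_late=int(r.l_late),
            height_max=float(r.height_max_m),
            lai_max=float(r.lai_max),
            root_depth_max=float(r.root_depth_max_mm),
        )
    return crops


def load_schedules(path: str | Path | None = None) -> dict[str, tuple[IrrigationEvent, ...]]:
    """Irrigation schedules keyed by crop name."""
    df = pd.read_csv(path) if path is not None else _data("irrigation.csv")
    out: dict[str, tuple[IrrigationEvent, ...]] = {}
    for crop, grp in df.groupby("crop", sort=False):
        out[str(crop)] = tuple(
            IrrigationEvent(month=int(r.month), day=int(r.day), depth=float(r.quota_mm))
            for r in grp.itertuples(index=False)
        )
    return out


def load_scenarios(path: str | Path | None = None) -> dict[str, Scenario]:
    """Planting scenarios (current situation, scenario 1, scenario 2)."""
    df = pd.read_csv(path) if path is not None else _data("scenarios.csv")
    out: dict[str, Scenario] = {}
    for col, label in [
        ("current", "current"),
        ("scenario_1", "scenario 1"),
        ("scenario_2", "scenario 2"),
    ]:
        props = {str(r.crop): float(getattr(r, col)) / 100.0 for r in df.itertuples(index=False)}
        out[label] = Scenario(name=label, proportions=props)
    return out


def load_economics(path: str | Path | None = None) -> dict[str, EconRecord]:
    """Per-crop yield/price/input-cost records."""
    df = pd.read_csv(path) if path is not None else _data("economics.csv")
    return {
        str(r.crop): EconRecord(
            crop=str(r.crop),
            yield_kg_hm2=float(r.yield_kg_hm2),
            price_yuan_kg=float(r.price_yuan_kg),
            unit_input_yuan_hm2=float(r.unit_input_yuan_hm2),
        )
        for r in df.itertuples(index=False)
    }


def load_parameter_table() -> pd.DataFrame:
    """Sensitivity-parameter table (ranges, calibrated values, published ranks)."""
    return _data("parameters.csv")


TOTAL_CULTIVATED_AREA_HM2 = 23393.1


def load_fixture_tables():
    """All packaged district tables at once.

    Returns (soils, crops, schedules, scenarios, econ, params) where params
    is a :class:`ModelParams` built from the calibrated column of the
    sensitivity table.
    """
    soils = load_soils()
    crops = load_crops()
    schedules = load_schedules()
    scenarios = load_scenarios()
    econ = load_economics()
    tab = load_parameter_table().set_index("parameter")["calibrated"]
    params = ModelParams(
        esco=float(tab["esco"]),
        canmx=float(tab["canmx"]),
        gw_revap=float(tab["gw_revap"]),
        epco=float(tab["epco"]),
        sol_awc_scale=float(tab["sol_awc_scale"]),
    )
    return soils, crops, schedules, scenarios, econ, params
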