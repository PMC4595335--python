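"""Seeded stochastic daily weather for a temperate-continental arid site.

The generator emulates the study district's stated climate: roughly
150–160 mm of annual precipitation with 80–85% falling April–September, a
7.7 °C annual mean temperature, dry air and moderate wind. Precipitation
occurrence follows a two-state Markov chain with monthly parameters whose
stationary wet-day frequencies, combined with exponential wet-day amounts,
reproduce the prescribed monthly climatological totals in expectation.
Temperature is a sinusoid over the year plus Gaussian noise; humidity is
higher on wet days; wind is lognormal. Solar radiation is left unset and
estimated downstream from the diurnal temperature range.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .types import ValidationError, WeatherDay

# relative monthly precipitation weights (Jan..Dec); Apr–Sep vs the rest are
# rescaled separately to hit the configured seasonal share
_MONTH_WEIGHTS = np.array([2.0, 3.0, 6.0, 10.0, 17.0, 22.0, 30.0, 30.0, 19.0, 9.0, 4.0, 3.0])
_APR_SEP = np.zeros(12, dtype=bool)
_APR_SEP[3:9] = True


@dataclass(frozen=True)
class ClimateSpec:
    """Target climate statistics and distribution parameters."""

    annual_precip_mean: float = 155.0     # mm
    apr_sep_fraction: float = 0.825
    tmean_annual: float = 7.7             # °C
    temp_amplitude: float = 13.5          # °C, seasonal half-range
    temp_noise_sd: float = 1.5
    diurnal_range_mean: float = 13.0      # °C
    diurnal_range_sd: float = 2.0
    rh_mean_dry: float = 45.0             # %
    rh_mean_wet_boost: float = 15.0
    rh_sd: float = 8.0
    rh_min_ratio: float = 0.55            # rh_min ≈ ratio · rh_mean
    wind_mean: float = 2.0                # m/s
    wind_sigma: float = 0.4               # lognormal shape
    wet_persistence: float = 0.15         # p11 − stationary wet frequency
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.apr_sep_fraction < 1.0:
            raise ValidationError("apr_sep_fraction must be in (0, 1)")
        if self.annual_precip_mean <= 0:
            raise ValidationError("annual_precip_mean must be positive")


def monthly_precip_targets(spec: ClimateSpec) -> np.ndarray:
    """Climatological monthly precipitation totals (mm) implied by the spec."""
    w = _MONTH_WEIGHTS.copy()
    in_sum = w[_APR_SEP].sum()
    out_sum = w[~_APR_SEP].sum()
    targets = np.empty(12)
    targets[_APR_SEP] = w[_APR_SEP] / in_sum * spec.annual_precip_mean * spec.apr_sep_fraction
    targets[~_APR_SEP] = (
        w[~_APR_SEP] / out_sum * spec.annual_precip_mean * (1.0 - spec.apr_sep_fraction)
    )
    return targets


_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MEAN_WET_AMOUNT = np.array([1.2, 1.2, 1.8, 2.2, 2.8, 3.2, 3.8, 3.8, 3.0, 2.2, 1.5, 1.2])


def _markov_params(spec: ClimateSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-month (p01, p11, wet-day mean amount) hitting the monthly targets."""
    targets = monthly_precip_targets(spec)
    pw = np.clip(targets / (_DAYS_IN_MONTH * _MEAN_WET_AMOUNT), 0.02, 0.6)
    amounts = targets / (_DAYS_IN_MONTH * pw)
    p11 = np.clip(pw + spec.wet_persistence, 0.05, 0.95)
    p01 = np.clip(pw * (1.0 - p11) / (1.0 - pw), 0.005, 0.95)
    # re-derive the stationary frequency implied by (p01, p11) and rescale
    # amounts so expected totals still match the targets
    pw_stat = p01 / (1.0 + p01 - p11)
    amounts = targets / (_DAYS_IN_MONTH * pw_stat)
    return p01, p11, amounts


def generate_weather(spec: ClimateSpec = ClimateSpec(), years: int = 1, start_year: int = 2001) -> list[WeatherDay]:
    """Generate a daily series of the given number of calendar years."""
    if years < 1:
        raise ValidationError("years must be >= 1")
    rng = np.random.default_rng(spec.seed)
    p01, p11, amounts = _markov_params(spec)
    days: list[WeatherDay] = []
    wet_prev = False
    date = dt.date(start_year, 1, 1)
    end = dt.date(start_year + years, 1, 1)
    while date < end:
        m = date.month - 1
        doy = date.timetuple().tm_yday
        p_wet = p11[m] if wet_prev else p01[m]
        wet = rng.random() < p_wet
        precip = float(rng.exponential(amounts[m])) if wet else 0.0
        wet_prev = wet

        tmean = (
            spec.tmean_annual
            + spec.temp_amplitude * math.cos(2.0 * math.pi * (doy - 199) / 365.25)
            + float(rng.normal(0.0, spec.temp_noise_sd))
        )
        trange = max(float(rng.normal(spec.diurnal_range_mean, spec.diurnal_range_sd)), 4.0)
        if wet:
            trange *= 0.7

        rh_mean = float(
            np.clip(
                rng.normal(spec.rh_mean_dry + spec.rh_mean_wet_boost * wet, spec.rh_sd),
                15.0,
                95.0,
            )
        )
        rh_min = float(np.clip(rh_mean * rng.uniform(spec.rh_min_ratio - 0.1, spec.rh_min_ratio + 0.1), 5.0, rh_mean))
        wind = float(
            rng.lognormal(math.log(spec.wind_mean) - 0.5 * spec.wind_sigma**2, spec.wind_sigma)
        )
        days.append(
            WeatherDay(
                date=date,
                precip=round(precip, 3),
                tmax=round(tmean + trange / 2.0, 2),
                tmin=round(tmean - trange / 2.0, 2),
                rh_mean=round(rh_mean, 1),
                rh_min=round(rh_min, 1),
                wind_u2=round(wind, 2),
            )
        )
        date += dt.timedelta(days=1)
    return days


def climate_summary(days: list[WeatherDay]) -> dict[str, float]:
    """Recovered climate statistics of a generated (or loaded) series."""
    years = {d.date.year for d in days}
    total = math.fsum(d.precip for d in days)
    apr_sep = math.fsum(d.precip for d in days if 4 <= d.date.month <= 9)
    return {
        "annual_precip_mean_mm": total / len(years),
        "apr_sep_fraction": apr_sep / total if total > 0 else float("nan"),
        "tmean_c": math.fsum(d.tmean for d in days) / len(days),
        "wind_mean_m_s": math.fsum(d.wind_u2 for d in days) / len(days),
    }
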