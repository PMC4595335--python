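"""Seasonal crop development curves.

The published district data give basal crop coefficients per stage but no
canopy dynamics, so leaf area index, crop height and rooting depth follow
simple stage-indexed shapes: LAI rises linearly from emergence to its
maximum over the initial + development stages, holds through mid-season and
declines linearly during late season; height grows to its maximum over the
same window; roots deepen linearly to their maximum by the end of the
development stage.
"""

from __future__ import annotations

import datetime as dt

from .types import CropParams

BARE_SOIL_HEIGHT_M = 0.1     # aerodynamic height used out of season
ROOT_DEPTH_MIN_MM = 150.0    # seedling root depth at planting
LAI_END_FRACTION = 0.2       # LAI retained at the end of late season


def day_of_season(crop: CropParams, date: dt.date) -> int | None:
    """0-based day since planting, or None outside the growing season."""
    planting = crop.planting_date(date.year)
    dos = (date - planting).days
    if 0 <= dos < crop.season_length:
        return dos
    return None


def lai(crop: CropParams, dos: int | None) -> float:
    """Leaf area index on a given day of season (0 when fallow)."""
    if dos is None:
        return 0.0
    grow = crop.l_ini + crop.l_dev
    mid_end = grow + crop.l_mid
    if dos < grow:
        return crop.lai_max * (dos + 1) / grow
    if dos < mid_end:
        return crop.lai_max
    frac_late = (dos - mid_end + 1) / crop.l_late
    return crop.lai_max * (1.0 - (1.0 - LAI_END_FRACTION) * frac_late)


def height(crop: CropParams, dos: int | None) -> float:
    """Crop height (m); a small bare-soil roughness height when fallow."""
    if dos is None:
        return BARE_SOIL_HEIGHT_M
    grow = crop.l_ini + crop.l_dev
    frac = min(1.0, (dos + 1) / grow)
    return max(BARE_SOIL_HEIGHT_M, crop.height_max * frac)


def root_depth(crop: CropParams, dos: int | None) -> float:
    """Rooting depth (mm); minimal when fallow (residual root zone)."""
    if dos is None:
        return ROOT_DEPTH_MIN_MM
    grow_end = crop.l_ini + crop.l_dev
    frac = min(1.0, (dos + 1) / grow_end)
    return ROOT_DEPTH_MIN_MM + (crop.root_depth_max - ROOT_DEPTH_MIN_MM) * frac
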