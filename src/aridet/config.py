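"""Run configuration: one YAML file referencing CSV tables by path.

Any table left out of the config falls back to the packaged district
fixture. Paths are resolved relative to the config file. Example:

```yaml
tables:
  soils: my_soils.csv
  weather: weather_1990_2011.csv
params:
  esco: 0.875
  canmx: 9.853
options:
  module: dualkc
  kr_method: modified
  et0_method: pm
  spinup: 1
site:
  latitude_deg: 37.9
  elevation_m: 1550
soil_shares:
  Grey desert soil: 0.30
  Irrigated desert soil: 0.40
  Aeolian sandy soil: 0.10
  Sierozem: 0.20
```
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as aio
from .reference_et import Site
from .types import CropParams, EconRecord, ModelParams, Scenario, SoilProfile


@dataclass
class SimulationConfig:
    soils: dict[str, SoilProfile]
    crops: dict[str, CropParams]
    schedules: dict
    scenarios: dict[str, Scenario]
    econ: dict[str, EconRecord]
    params: ModelParams
    site: Site = Site()
    soil_shares: dict[str, float] | None = None
    weather_path: Path | None = None
    options: dict = field(default_factory=dict)


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig`; with no path, all-fixture defaults."""
    if path is None:
        soils, crops, schedules, scenarios, econ, params = aio.load_fixture_tables()
        return SimulationConfig(soils, crops, schedules, scenarios, econ, params)
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise aio.ConfigError(f"{path}: top level must be a mapping")
    base = path.parent
    tables = raw.get("tables", {}) or {}

    def resolve(key: str) -> Path | None:
        p = tables.get(key)
        return (base / p) if p is not None else None

    params_kw = raw.get("params", {}) or {}
    params = ModelParams(**params_kw)
    soils = aio.load_soils(resolve("soils"), awc_scale=params.sol_awc_scale)
    crops = aio.load_crops(resolve("kcb"), resolve("phenology"))
    schedules = aio.load_schedules(resolve("irrigation"))
    scenarios = aio.load_scenarios(resolve("scenarios"))
    econ = aio.load_economics(resolve("economics"))
    site_kw = raw.get("site", {}) or {}
    return SimulationConfig(
        soils=soils,
        crops=crops,
        schedules=schedules,
        scenarios=scenarios,
        econ=econ,
        params=params,
        site=Site(**site_kw),
        soil_shares=raw.get("soil_shares"),
        weather_path=(base / raw["tables"]["weather"]) if tables.get("weather") else None,
        options=raw.get("options", {}) or {},
    )
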