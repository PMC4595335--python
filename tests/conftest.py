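import pytest

from aridet import HRU, load_fixture_tables
from aridet.weather_gen import ClimateSpec, generate_weather

GOLDEN_SEED = 20151006


@pytest.fixture(scope="session")
def tables():
    soils, crops, schedules, scenarios, econ, params = load_fixture_tables()
    return {
        "soils": soils,
        "crops": crops,
        "schedules": schedules,
        "scenarios": scenarios,
        "econ": econ,
        "params": params,
    }


@pytest.fixture(scope="session")
def weather_3y():
    return generate_weather(ClimateSpec(seed=GOLDEN_SEED), years=3)


@pytest.fixture(scope="session")
def maize_hru(tables):
    return HRU(
        id="maize/irrigated-desert",
        area=1.0,
        soil=tables["soils"]["Irrigated desert soil"],
        crop=tables["crops"]["Summer maize"],
        schedule=tables["schedules"]["Summer maize"],
    )
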