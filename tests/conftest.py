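import os
import sys

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, os.path.dirname(__file__))

import coldhardiness as ch

settings.register_profile(
    "derandomized",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def yabukita() -> ch.ModelParams:
    return ch.load_params("yabukita")


@pytest.fixture(scope="session")
def yutakamidori() -> ch.ModelParams:
    return ch.load_params("yutakamidori")


@pytest.fixture(scope="session")
def one_season_weather() -> pd.DataFrame:
    """One kagoshima-like hardiness season (1 July - 30 June)."""
    return ch.generate_weather(ch.kagoshima_like(2015, 1, seed=3))


@pytest.fixture(scope="session")
def five_season_weather() -> pd.DataFrame:
    return ch.generate_weather(ch.kagoshima_like(2010, 5, seed=7))
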