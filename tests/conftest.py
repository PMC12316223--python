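import numpy as np
import pandas as pd
import pytest

from paddysim.cultivars import CULTIVARS
from paddysim.simulator import SimConfig, SoilProfile, prepare_forcing
from paddysim.weather import (
    AUTUMN_DEFAULT,
    SPRING_DEFAULT,
    DailyWeatherSeries,
    generate_season_weather,
)


@pytest.fixture(scope="session")
def spring_weather():
    return generate_season_weather(SPRING_DEFAULT.with_year(2001, 450.0), seed=101)


@pytest.fixture(scope="session")
def autumn_weather():
    return generate_season_weather(AUTUMN_DEFAULT.with_year(2001, 500.0), seed=202)


@pytest.fixture(scope="session")
def spring_forcing(spring_weather):
    return prepare_forcing(spring_weather)


@pytest.fixture(scope="session")
def tk9():
    return CULTIVARS["TK9"]


@pytest.fixture(scope="session")
def tng67():
    return CULTIVARS["TNG67"]


def constant_weather(n_days=140, tmax=25.0, tmin=15.0, rain=0.0, srad=15.0, year=2001, doy=61):
    """A flat synthetic series for closed-form phenology/water checks."""
    start = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1)
    return DailyWeatherSeries(
        pd.DataFrame(
            {
                "date": pd.date_range(start, periods=n_days, freq="D"),
                "day": np.arange(n_days),
                "tmax": tmax,
                "tmin": tmin,
                "tavg": np.nan,
                "rain": rain,
                "srad": srad,
            }
        )
    )
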