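import numpy as np
import pandas as pd
import pytest

from paddysim import generate_weather, load_cultivars, load_soil_profile
from paddysim.soil import SoilLayer, SoilProfile
from paddysim.weather import WeatherSeries


@pytest.fixture(scope="session")
def profile():
    return load_soil_profile()


@pytest.fixture(scope="session")
def cultivars():
    return load_cultivars()


@pytest.fixture(scope="session")
def mtu(cultivars):
    return cultivars["MTU7029"]


@pytest.fixture(scope="session")
def arize(cultivars):
    return cultivars["Arize6129"]


@pytest.fixture(scope="session")
def weather_10y():
    return generate_weather(n_years=10, seed=1234)


@pytest.fixture
def uniform_profile():
    """Single-texture profile with round numbers, for arithmetic checks."""
    layers = (
        SoilLayer(0, 15, ll=0.10, dul=0.30, sat=0.40),
        SoilLayer(15, 30, ll=0.10, dul=0.30, sat=0.40),
        SoilLayer(30, 60, ll=0.10, dul=0.30, sat=0.40),
    )
    return SoilProfile(layers=layers)


def _make_series(rain, year=2001, latitude=25.59, tmax=32.0, tmin=24.0, srad=18.0):
    """Constructed weather series from a rain array (constant temperatures)."""
    n = len(rain)
    dates = pd.date_range(f"{year}-01-01", periods=n, freq="D")
    df = pd.DataFrame(
        {
            "date": dates,
            "tmax": np.full(n, tmax),
            "tmin": np.full(n, tmin),
            "rain": np.asarray(rain, dtype=float),
            "sunshine": np.full(n, 6.0),
            "srad": np.full(n, srad),
        }
    )
    return WeatherSeries(df, latitude)


@pytest.fixture
def make_series():
    return _make_series
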