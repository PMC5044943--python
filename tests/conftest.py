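import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wheatclim.generator import SyntheticWeatherConfig, generate_weather, preset
from wheatclim.phenology import CropParameters
from wheatclim.weather import WeatherSeries


@pytest.fixture
def make_series():
    """Factory for simple deterministic weather series."""

    def _make(
        t_mean,
        prec=0.0,
        start="2000-09-01",
        days=None,
        site="TEST",
    ) -> WeatherSeries:
        if np.isscalar(t_mean):
            assert days is not None
            t = np.full(days, float(t_mean))
        else:
            t = np.asarray(t_mean, float)
            days = len(t)
        p = np.full(days, float(prec)) if np.isscalar(prec) else np.asarray(prec, float)
        idx = pd.date_range(start, periods=days, freq="D")
        return WeatherSeries.from_arrays(site, idx, t, p)

    return _make


@pytest.fixture
def params() -> CropParameters:
    return CropParameters()


@pytest.fixture(scope="session")
def dh_series() -> WeatherSeries:
    """One reference-climate synthetic series reused across tests."""
    return generate_weather(preset("DH-SCEN", seed=1), 1980, 2010)


def naive_harvest_date(series, sowing_date, params):
    """Independent day-at-a-time oracle for the heat-sum harvest date."""
    total = 0.0
    day = sowing_date
    horizon = dt.date(sowing_date.year + 1, 12, 31)
    frame = series.frame
    while day <= min(horizon, series.end):
        t = float(frame.loc[pd.Timestamp(day), "t_mean"])
        if t >= params.t_base:
            total += t - params.t_base
        if total >= params.t_h:
            return day
        day += dt.timedelta(days=1)
    return None
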