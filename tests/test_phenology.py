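import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import naive_harvest_date
from wheatclim.generator import SyntheticWeatherConfig, generate_weather, preset
from wheatclim.phenology import (
    CropParameters,
    accumulate_gdd,
    cold_days,
    count_vegetation_days,
    growing_period_length,
    harvest_date,
    moving_average_temp,
    round_half_away,
    run_phenology,
    v_per_formula,
)
from wheatclim.pipeline import per_year_metrics
from wheatclim.weather import WeatherConfigError, WeatherInputError


class TestMovingAverage:
    def test_constant_series_is_fixed_point(self, make_series):
        s = make_series(7.0, days=30)
        sm = moving_average_temp(s, 5)
        assert np.allclose(sm.values.to_numpy(), 7.0)

    def test_centre_of_arithmetic_sequence(self, make_series):
        s = make_series([1, 2, 3, 4, 5])
        sm = moving_average_temp(s, 5)
        assert sm.values.iloc[2] == pytest.approx(3.0)

    def test_edges_truncate_to_available_days(self, make_series):
        s = make_series([10, 0, 0, 0, 10])
        sm = moving_average_temp(s, 5)
        assert sm.values.iloc[2] == pytest.approx(4.0)
        assert sm.values.iloc[0] == pytest.approx(10.0 / 3.0)
        assert sm.values.iloc[-1] == pytest.approx(10.0 / 3.0)

    def test_even_window_rejected(self, make_series):
        with pytest.raises(WeatherConfigError, match="odd"):
            moving_average_temp(make_series(5.0, days=10), 4)


class TestAccumulateGdd:
    def test_constant_increment(self, make_series, params):
        s = make_series(12.5, days=30, start="2000-01-01")
        trace = accumulate_gdd(s, dt.date(2000, 1, 1), params)
        assert trace.iloc[9] == pytest.approx(100.0)  # 10 deg-days per day

    def test_below_base_accrues_nothing(self, make_series, params):
        s = make_series(2.0, days=20, start="2000-01-01")
        trace = accumulate_gdd(s, dt.date(2000, 1, 1), params)
        assert np.all(trace.to_numpy() == 0.0)

    def test_day_by_day_values(self, make_series, params):
        s = make_series([5.0, 1.0, 4.0], start="2000-01-01")
        trace = accumulate_gdd(s, dt.date(2000, 1, 1), params)
        assert trace.to_numpy() == pytest.approx([2.5, 2.5, 4.0])

    def test_sowing_outside_series_rejected(self, make_series, params):
        s = make_series(5.0, days=10, start="2000-01-01")
        with pytest.raises(WeatherInputError, match="outside"):
            accumulate_gdd(s, dt.date(1999, 12, 31), params)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-30, max_value=45, allow_nan=False),
            min_size=1,
            max_size=120,
        )
    )
    def test_trace_non_decreasing_and_non_negative(self, temps):
        from wheatclim.weather import WeatherSeries

        idx = pd.date_range("2000-01-01", periods=len(temps))
        s = WeatherSeries.from_arrays("H", idx, temps, np.zeros(len(temps)))
        trace = accumulate_gdd(s, dt.date(2000, 1, 1), CropParameters())
        arr = trace.to_numpy()
        assert arr[0] >= 0
        assert np.all(np.diff(arr) >= 0)


class TestHarvestDate:
    def test_constant_warm_series_reaches_threshold_on_day_210(
        self, make_series, params
    ):
        sow = dt.date(2000, 9, 15)
        s = make_series(12.5, days=600, start="2000-09-15")
        d, trace = harvest_date(s, sow, params)
        assert (d - sow).days + 1 == 210  # sowing day counts as day 1
        assert trace.iloc[-1] >= params.t_h
        assert trace.iloc[-2] < params.t_h

    def test_zero_threshold_harvests_on_sowing_day(self, make_series):
        p = CropParameters(t_h=0.0)
        sow = dt.date(2000, 9, 15)
        s = make_series(12.5, days=100, start="2000-09-15")
        d, _ = harvest_date(s, sow, p)
        assert d == sow

    def test_cold_series_is_censored(self, make_series, params):
        sow = dt.date(2000, 9, 15)
        s = make_series(2.0, days=900, start="2000-01-01")
        d, _ = harvest_date(s, sow, params)
        assert d is None

    def test_search_stops_at_end_of_harvest_year(self, make_series, params):
        # barely-warm series that would cross the threshold only after the
        # December 31 horizon of the year following sowing
        sow = dt.date(2000, 9, 15)
        s = make_series(6.0, days=1200, start="2000-09-01")
        d, trace = harvest_date(s, sow, params)
        assert d is None
        assert trace.index[-1].date() == dt.date(2001, 12, 31)


class TestGrowingPeriodLength:
    def test_day_of_year_formula(self):
        assert v_per_formula(258, 216) == pytest.approx(323.25)
        assert v_per_formula(1, 1) == pytest.approx(365.25)

    def test_both_conventions_for_a_real_season(self):
        # non-leap sowing year: Sep 15 is day 258, Aug 4 is day 216
        paper, exact = growing_period_length(
            dt.date(2001, 9, 15), dt.date(2002, 8, 4)
        )
        assert paper == pytest.approx(323.25)
        assert exact == 324  # endpoint-inclusive calendar count

    def test_harvest_before_sowing_rejected(self):
        with pytest.raises(WeatherInputError):
            growing_period_length(dt.date(2001, 9, 15), dt.date(2001, 9, 15))

    @pytest.mark.parametrize(
        "x,expected", [(323.25, 323), (323.5, 324), (-3.5, -4), (0.25, 0)]
    )
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestVegetationAndColdDays:
    def test_all_warm_period_counts_every_day(self, make_series, params):
        s = make_series(10.0, days=50, start="2000-01-01")
        sm = moving_average_temp(s, 5)
        n = count_vegetation_days(sm, dt.date(2000, 1, 1), dt.date(2000, 1, 20), params)
        assert n == 20

    def test_all_cold_period_counts_none(self, make_series, params):
        s = make_series(2.5, days=50, start="2000-01-01")  # exactly at base: cold
        sm = moving_average_temp(s, 5)
        n = count_vegetation_days(sm, dt.date(2000, 1, 1), dt.date(2000, 1, 20), params)
        assert n == 0

    def test_alternating_smoothed_series(self, make_series, params):
        from wheatclim.phenology import SmoothedTemperature

        idx = pd.date_range("2000-01-01", periods=10)
        smoothed = SmoothedTemperature(
            pd.Series([5.0, 0.0] * 5, index=idx), window=5
        )
        n = count_vegetation_days(
            smoothed, dt.date(2000, 1, 1), dt.date(2000, 1, 10), params
        )
        assert n == 5

    def test_coverage_gap_rejected(self, make_series, params):
        s = make_series(5.0, days=10, start="2000-01-01")
        sm = moving_average_temp(s, 5)
        with pytest.raises(WeatherInputError, match="cover"):
            count_vegetation_days(
                sm, dt.date(2000, 1, 1), dt.date(2000, 2, 1), params
            )

    @pytest.mark.parametrize(
        "v_per,v_day,expected", [(324, 267, 57), (323, 246, 77), (100, 100, 0)]
    )
    def test_cold_day_arithmetic(self, v_per, v_day, expected):
        assert cold_days(v_per, v_day) == expected

    def test_negative_cold_days_is_internal_error(self):
        with pytest.raises(ValueError, match="inconsistency"):
            cold_days(10, 11)


class TestRunPhenology:
    def test_constant_warm_season(self, make_series):
        s = make_series(12.5, days=1000, start="2000-01-01")
        (season,) = run_phenology(s, [2001])
        assert not season.censored
        assert (season.harvest_date - season.sowing_date).days + 1 == 210
        assert season.v_day == season.v_per_exact  # no cold days
        assert season.cold_days == 0

    def test_cold_series_censored(self, make_series):
        s = make_series(2.0, days=1000, start="2000-01-01")
        (season,) = run_phenology(s, [2001])
        assert season.censored
        assert season.harvest_date is None and season.v_day is None

    def test_multi_season_run_in_year_order(self, dh_series):
        seasons = run_phenology(dh_series, range(1981, 1991))
        assert [s.season for s in seasons] == list(range(1981, 1991))

    def test_insufficient_coverage_names_season(self, make_series):
        s = make_series(12.5, days=200, start="2000-01-01")
        with pytest.raises(WeatherInputError, match="2001"):
            run_phenology(s, [2001])

    def test_cold_day_identity_on_synthetic_seasons(self, dh_series):
        for s in run_phenology(dh_series, range(1981, 2011)):
            assert not s.censored
            assert s.cold_days + s.v_day == s.v_per_exact
            assert 0 <= s.v_day <= s.v_per_exact


class TestOracleAndMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_harvest_matches_day_loop_oracle(self, seed, params):
        cfg = SyntheticWeatherConfig(seed=seed, t_annual_mean=8.0 + seed * 0.4)
        series = generate_weather(cfg, 2000, 2001)
        sow = dt.date(2000, 9, 15)
        ours, _ = harvest_date(series, sow, params)
        assert ours == naive_harvest_date(series, sow, params)

    @pytest.mark.parametrize("delta", [0.5, 2.0, 5.0])
    def test_uniform_warming_never_delays_harvest(self, delta, params):
        import dataclasses

        base = SyntheticWeatherConfig(seed=99)
        warm = dataclasses.replace(base, warming_per_slot=delta)
        sow = dt.date(2000, 9, 15)
        d0, _ = harvest_date(generate_weather(base, 2000, 2001), sow, params)
        d1, _ = harvest_date(generate_weather(warm, 2000, 2001), sow, params)
        assert d0 is not None and d1 is not None
        assert d1 <= d0

    def test_warmer_slot_shortens_mean_growing_period(self, dh_series):
        warm = generate_weather(preset("DH-TMED", seed=1), 1980, 2010)
        cold_tab = per_year_metrics(dh_series, range(1981, 2011))
        warm_tab = per_year_metrics(warm, range(1981, 2011))
        assert warm_tab["v_per"].mean() < cold_tab["v_per"].mean()
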