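"""Thermal-time phenology of winter wheat.

The harvest date is predicted purely from air temperature: growing degree
days (GDD) accumulate from sowing as ``max(T_mean − T_base, 0)`` per day,
and the crop is harvest-ripe on the first day the cumulative sum reaches a
threshold heat sum T_h.  Defaults are T_base = 2.5 °C, T_h = 2100 °C·d and
sowing on September 15, the common values for rainfed winter wheat in the
North German Plain.

From sowing and harvest dates the module derives:

* the growing-period length V_per, in two conventions: the day-of-year
  formula ``JD_h + (365¼ − JD_s)`` traditionally used for winter crops that
  straddle New Year ("paper mode", fractional), and the exact
  endpoint-inclusive calendar day count;
* vegetation days V_day — days within the growing period whose *smoothed*
  mean temperature (centred 5-day simple moving average) strictly exceeds
  T_base;
* cold days — growing-period days that are not vegetation days, a proxy for
  interruptions of biomass accumulation (relevant e.g. to vernalisation).

Seasons in which the heat sum is never reached before December 31 of the
harvest year are *censored*: flagged, never imputed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .weather import WeatherSeries, WeatherInputError, WeatherConfigError

__all__ = [
    "CropParameters",
    "SmoothedTemperature",
    "SeasonPhenology",
    "moving_average_temp",
    "accumulate_gdd",
    "harvest_date",
    "growing_period_length",
    "v_per_formula",
    "count_vegetation_days",
    "cold_days",
    "run_phenology",
    "phenology_frame",
    "round_half_away",
]

#: days per year including the leap-day quarter, the classical constant of
#: the winter-crop growing-period formula
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CropParameters:
    """Constants of the thermal-time model.

    t_base:
        Base temperature (°C) below which a day contributes no thermal
        time.  Default 2.5 °C (between literature optima for root growth,
        3 °C, and shoot growth, 2 °C).
    t_h:
        Threshold heat sum (°C·d) at which the crop is harvest-ripe.
        Default 2100 °C·d, a fit parameter valid across the study region.
    sowing_month, sowing_day:
        Calendar sowing date, applied in the year before harvest.
        Default September 15.
    smoothing_window:
        Width (odd, days) of the moving average used for vegetation-day
        counting.  Default 5.
    """

    t_base: float = 2.5
    t_h: float = 2100.0
    sowing_month: int = 9
    sowing_day: int = 15
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_base):
            raise WeatherConfigError("t_base must be finite")
        if not (self.t_h >= 0 and math.isfinite(self.t_h)):
            raise WeatherConfigError("t_h must be >= 0 and finite")
        # validate the month/day combination on a non-leap year
        dt.date(2001, self.sowing_month, self.sowing_day)
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise WeatherConfigError("smoothing_window must be odd and >= 1")

    def sowing_date(self, harvest_year: int) -> dt.date:
        """Sowing date of the season harvested in ``harvest_year``."""
        return dt.date(harvest_year - 1, self.sowing_month, self.sowing_day)


@dataclass(frozen=True)
class SmoothedTemperature:
    """Per-day smoothed mean temperature, aligned to the source series dates."""

    values: pd.Series  # DatetimeIndex -> °C
    window: int

    def over(self, start: dt.date, end: dt.date) -> pd.Series:
        sel = self.values.loc[pd.Timestamp(start) : pd.Timestamp(end)]
        expected = (end - start).days + 1
        if len(sel) != expected:
            raise WeatherInputError(
                f"smoothed temperature does not cover {start}..{end}"
            )
        return sel


@dataclass(frozen=True)
class SeasonPhenology:
    """Per-season phenology outputs for one harvest year."""

    season: int  # harvest year label
    sowing_date: dt.date
    harvest_date: dt.date | None
    censored: bool
    v_per_paper: float | None  # JD_h + (365.25 - JD_s)
    v_per_exact: int | None  # endpoint-inclusive calendar days
    v_day: int | None
    cold_days: int | None
    gdd_trace: pd.Series = field(repr=False, compare=False, default=None)

    @property
    def harvest_doy(self) -> int | None:
        return None if self.harvest_date is None else self.harvest_date.timetuple().tm_yday


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def moving_average_temp(
    series: WeatherSeries, window: int = 5
) -> SmoothedTemperature:
    """Centred simple moving average of daily mean temperature.

    At the series edges the window truncates to the available days, so the
    first value of a 5-day window averages days 1–3.  A constant series maps
    to itself.
    """
    if window % 2 == 0:
        raise WeatherConfigError(f"window must be odd, got {window}")
    if window < 1 or window > len(series):
        raise WeatherConfigError(
            f"window must be in [1, {len(series)}], got {window}"
        )
    sm = (
        series.frame["t_mean"]
        .rolling(window=window, center=True, min_periods=1)
        .mean()
    )
    sm.name = "t_mav"
    return SmoothedTemperature(values=sm, window=window)


def _gdd_increments(t_mean: np.ndarray, t_base: float) -> np.ndarray:
    return np.maximum(t_mean - t_base, 0.0)


def accumulate_gdd(
    series: WeatherSeries,
    sowing_date: dt.date,
    params: CropParameters,
    *,
    end: dt.date | None = None,
) -> pd.Series:
    """Cumulative growing-degree-day trace from the sowing day (inclusive).

    Each day contributes ``max(T_mean − T_base, 0)``; days below the base
    temperature add nothing.  The trace runs to ``end`` (default: series
    end) and is non-decreasing by construction.
    """
    if not (series.start <= sowing_date <= series.end):
        raise WeatherInputError(
            f"sowing date {sowing_date} outside series {series.start}..{series.end}"
        )
    stop = series.end if end is None else min(end, series.end)
    win = series.window(sowing_date, stop)
    inc = _gdd_increments(win["t_mean"].to_numpy(), params.t_base)
    trace = pd.Series(np.cumsum(inc), index=win.index, name="gdd")
    return trace


def harvest_date(
    series: WeatherSeries,
    sowing_date: dt.date,
    params: CropParameters,
) -> tuple[dt.date | None, pd.Series]:
    """First date on which cumulative GDD reaches the heat-sum threshold.

    The search horizon ends on December 31 of the year after sowing (a
    wheat season never spans two summers); if the threshold is not reached
    by then — or the series ends first — the season is censored and the
    date is ``None``.  Returns ``(date_or_None, gdd_trace)``.
    """
    horizon = dt.date(sowing_date.year + 1, 12, 31)
    trace = accumulate_gdd(series, sowing_date, params, end=horizon)
    hit = trace.index[trace.to_numpy() >= params.t_h]
    if len(hit) == 0:
        return None, trace
    d = hit[0].date()
    return d, trace.loc[: hit[0]]


def v_per_formula(jd_s: float, jd_h: float) -> float:
    """Growing-period length from day-of-year numbers: JD_h + (365¼ − JD_s)."""
    return jd_h + (DAYS_PER_YEAR - jd_s)


def growing_period_length(
    sowing_date: dt.date, harvest_date: dt.date
) -> tuple[float, int]:
    """Growing-period length in both conventions.

    Returns ``(v_per_paper, v_per_exact)``: the fractional day-of-year
    formula ``JD_h + (365¼ − JD_s)`` and the exact endpoint-inclusive
    calendar day count.  For a winter crop the harvest falls in the year
    after sowing.
    """
    if harvest_date <= sowing_date:
        raise WeatherInputError(
            f"harvest {harvest_date} not after sowing {sowing_date}"
        )
    jd_s = sowing_date.timetuple().tm_yday
    jd_h = harvest_date.timetuple().tm_yday
    paper = v_per_formula(jd_s, jd_h)
    exact = (harvest_date - sowing_date).days + 1
    return paper, exact


def count_vegetation_days(
    smoothed: SmoothedTemperature,
    sowing_date: dt.date,
    harvest_date: dt.date,
    params: CropParameters,
) -> int:
    """Days in [sowing, harvest] whose smoothed temperature strictly exceeds T_base.

    The inequality is strict: a day sitting exactly on the base temperature
    is a cold day.
    """
    window = smoothed.over(sowing_date, harvest_date)
    return int((window.to_numpy() > params.t_base).sum())


def cold_days(v_per_days: int, v_day: int) -> int:
    """Cold days as the complement of vegetation days in the growing period."""
    out = v_per_days - v_day
    if out < 0:
        raise ValueError(
            f"internal inconsistency: v_day={v_day} exceeds v_per={v_per_days}"
        )
    return out


def run_phenology(
    series: WeatherSeries,
    years: Sequence[int],
    params: CropParameters | None = None,
) -> list[SeasonPhenology]:
    """Run the full per-season phenology for a list of harvest years.

    For each harvest year ``y`` the season is sown on the configured date of
    ``y − 1``; the series must cover sowing through December 31 of ``y``.
    Censored seasons (threshold never reached) are flagged and carry no
    dates or counts.  The cold-day identity uses the exact endpoint-
    inclusive period length, so ``cold_days + v_day == v_per_exact`` holds
    for every non-censored season.
    """
    if params is None:
        params = CropParameters()
    smoothed = moving_average_temp(series, params.smoothing_window)
    out: list[SeasonPhenology] = []
    for year in years:
        sow = params.sowing_date(year)
        season_end = dt.date(year, 12, 31)
        if not series.covers(sow, season_end):
            raise WeatherInputError(
                f"season {year}: series must cover {sow}..{season_end}, "
                f"has {series.start}..{series.end}"
            )
        hdate, trace = harvest_date(series, sow, params)
        if hdate is None:
            out.append(
                SeasonPhenology(
                    season=year,
                    sowing_date=sow,
                    harvest_date=None,
                    censored=True,
                    v_per_paper=None,
                    v_per_exact=None,
                    v_day=None,
                    cold_days=None,
                    gdd_trace=trace,
                )
            )
            continue
        v_paper, v_exact = growing_period_length(sow, hdate)
        v_day = count_vegetation_days(smoothed, sow, hdate, params)
        out.append(
            SeasonPhenology(
                season=year,
                sowing_date=sow,
                harvest_date=hdate,
                censored=False,
                v_per_paper=v_paper,
                v_per_exact=v_exact,
                v_day=v_day,
                cold_days=cold_days(v_exact, v_day),
                gdd_trace=trace,
            )
        )
    return out


def phenology_frame(seasons: Sequence[SeasonPhenology]) -> pd.DataFrame:
    """Tabulate per-season phenology as a DataFrame indexed by harvest year."""
    rows = []
    for s in seasons:
        rows.append(
            {
                "season": s.season,
                "sowing_date": s.sowing_date,
                "harvest_date": s.harvest_date,
                "harvest_doy": s.harvest_doy,
                "censored": s.censored,
                "v_per_paper": s.v_per_paper,
                "v_per_exact": s.v_per_exact,
                "v_day": s.v_day,
                "cold_days": s.cold_days,
            }
        )
    return pd.DataFrame(rows).set_index("season")
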