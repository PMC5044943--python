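"""Hydrological-year precipitation accounting.

Water budgets here follow the DIN 4049 convention: the hydrological year
H_a runs from November 1 of one calendar year to October 31 of the next,
and is labelled by its ending calendar year (the year containing the summer
half, matching harvest-year labels).  Its winter half H_W spans November
through April — the leaching period in the North German Plain — and its
summer half May through October.

Two crop-related precipitation windows are provided:

* ``p_veg`` — rainfall over the whole growing period (sowing to harvest);
* ``p_m_veg`` — rainfall over the *main* growing period, May 1 (assumed end
  of leaching, start of significant transpiration) to the harvest date.
  This is the water-availability indicator of interest, since rain falling
  before spring mostly percolates past the root zone.

All window sums are endpoint-inclusive.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weather import WeatherSeries, WeatherInputError

__all__ = [
    "HydroYearSummary",
    "SeasonWater",
    "assign_hydro_period",
    "hydro_year_summaries",
    "hydro_year_frame",
    "calendar_year_precip",
    "winter_share",
    "p_m_veg",
    "p_veg",
    "season_water",
]

WINTER_MONTHS = frozenset({11, 12, 1, 2, 3, 4})


@dataclass(frozen=True)
class HydroYearSummary:
    """Precipitation totals of one complete hydrological year.

    ``p_ha = p_hw + p_hs`` exactly (same summation order); ``share_hw`` is
    ``None`` when the annual total is zero.
    """

    hydro_year: int
    p_ha: float
    p_hw: float
    p_hs: float
    share_hw: float | None


@dataclass(frozen=True)
class SeasonWater:
    """Growing-period precipitation for one harvest season."""

    season: int
    p_m_veg: float
    p_veg: float
    empty_m_veg_window: bool = False


def assign_hydro_period(date: dt.date) -> tuple[int, str]:
    """Map a calendar date to its (hydrological year, season).

    November–December belong to the *following* hydrological year; the
    winter season is November–April, the summer season May–October.
    """
    if date.month >= 11:
        return date.year + 1, "winter"
    season = "winter" if date.month <= 4 else "summer"
    return date.year, season


def _hydro_labels(index: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised hydro-year labels and winter mask for a DatetimeIndex."""
    month = index.month.to_numpy()
    year = index.year.to_numpy()
    hydro_year = np.where(month >= 11, year + 1, year)
    is_winter = (month >= 11) | (month <= 4)
    return hydro_year, is_winter


def hydro_year_summaries(series: WeatherSeries) -> list[HydroYearSummary]:
    """Summarise every *complete* hydrological year in the series.

    A hydrological year Y is complete when the series covers
    Nov 1 (Y−1) .. Oct 31 (Y); partial years at the edges are dropped.
    """
    idx = series.frame.index
    hydro_year, is_winter = _hydro_labels(idx)
    prec = series.frame["prec"].to_numpy()

    out: list[HydroYearSummary] = []
    for y in np.unique(hydro_year):
        start = dt.date(int(y) - 1, 11, 1)
        end = dt.date(int(y), 10, 31)
        if not series.covers(start, end):
            continue
        mask = hydro_year == y
        p_hw = float(prec[mask & is_winter].sum())
        p_hs = float(prec[mask & ~is_winter].sum())
        p_ha = p_hw + p_hs
        share = (p_hw / p_ha) if p_ha > 0 else None
        out.append(HydroYearSummary(int(y), p_ha, p_hw, p_hs, share))
    return out


def hydro_year_frame(series: WeatherSeries) -> pd.DataFrame:
    """Per-hydro-year totals as a DataFrame indexed by hydro year."""
    rows = [
        {
            "hydro_year": s.hydro_year,
            "p_ha": s.p_ha,
            "p_hw": s.p_hw,
            "p_hs": s.p_hs,
            "share_hw": s.share_hw,
        }
        for s in hydro_year_summaries(series)
    ]
    return pd.DataFrame(rows).set_index("hydro_year")


def calendar_year_precip(series: WeatherSeries) -> pd.Series:
    """Annual precipitation totals (Jan 1–Dec 31) for complete calendar years."""
    idx = series.frame.index
    totals = {}
    for y in np.unique(idx.year.to_numpy()):
        y = int(y)
        if series.covers(dt.date(y, 1, 1), dt.date(y, 12, 31)):
            mask = idx.year == y
            totals[y] = float(series.frame["prec"].to_numpy()[mask].sum())
    return pd.Series(totals, name="p_annual", dtype=float)


def winter_share(p_hw: float, p_ha: float) -> float | None:
    """Share of hydrological-year precipitation that falls in winter.

    Full precision; report tables round to two decimals.  Returns ``None``
    (undefined) for a zero annual total.
    """
    if p_ha == 0:
        return None
    return p_hw / p_ha


def p_m_veg(series: WeatherSeries, harvest_date: dt.date) -> float:
    """Main-growing-period precipitation: May 1 through harvest, inclusive.

    A harvest before May 1 (a degenerate, very early season) yields an
    empty window and 0 mm, with a warning.
    """
    may1 = dt.date(harvest_date.year, 5, 1)
    if harvest_date < may1:
        warnings.warn(
            f"harvest {harvest_date} precedes May 1; P_m-veg window empty",
            stacklevel=2,
        )
        return 0.0
    return float(series.window(may1, harvest_date)["prec"].sum())


def p_veg(series: WeatherSeries, sowing_date: dt.date, harvest_date: dt.date) -> float:
    """Growing-period precipitation: sowing through harvest, inclusive."""
    if harvest_date < sowing_date:
        raise WeatherInputError("harvest precedes sowing")
    return float(series.window(sowing_date, harvest_date)["prec"].sum())


def season_water(
    series: WeatherSeries, season: int, sowing_date: dt.date, harvest_date: dt.date
) -> SeasonWater:
    """Bundle both growing-period precipitation sums for one season."""
    may1 = dt.date(harvest_date.year, 5, 1)
    empty = harvest_date < may1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pm = p_m_veg(series, harvest_date)
    return SeasonWater(
        season=season,
        p_m_veg=pm,
        p_veg=p_veg(series, sowing_date, harvest_date),
        empty_m_veg_window=empty,
    )
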