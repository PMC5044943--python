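"""End-to-end orchestration: weather → phenology → water budget → slot summary.

``per_year_metrics`` turns one weather series into the per-year metric
table the slot aggregation consumes; ``run_slot`` and ``run_comparison``
wrap generation + analysis for synthetic scenario experiments.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd

from .generator import SyntheticWeatherConfig, generate_weather
from .hydro import calendar_year_precip, hydro_year_frame, season_water
from .phenology import CropParameters, phenology_frame, run_phenology
from .timeslots import SlotDefinition, SlotSummary, SlotDelta, compare_slots, summarize_slot
from .weather import WeatherSeries

__all__ = [
    "METRICS",
    "per_year_metrics",
    "run_slot",
    "run_comparison",
]

#: metric columns of the per-year table, in reporting order
METRICS = [
    "p_annual",
    "p_ha",
    "p_hw",
    "p_hs",
    "share_hw",
    "v_per",
    "v_per_paper",
    "v_day",
    "cold_days",
    "p_m_veg",
    "p_veg",
    "harvest_doy",
    "t_mean_annual",
]


def per_year_metrics(
    series: WeatherSeries,
    years: range | list[int],
    params: CropParameters | None = None,
) -> pd.DataFrame:
    """Assemble the per-year metric table for a list of harvest years.

    Index: year.  Phenology metrics of censored seasons are NaN (excluded
    downstream, never imputed); ``v_per`` is the exact endpoint-inclusive
    growing-period length, with the classical day-of-year formula kept in
    ``v_per_paper``.  Hydrological-year metrics are joined on the matching
    year label; ``t_mean_annual`` and ``p_annual`` are calendar-year
    statistics.
    """
    params = params or CropParameters()
    years = list(years)
    seasons = run_phenology(series, years, params)
    pheno = phenology_frame(seasons)

    hydro = hydro_year_frame(series)
    p_annual = calendar_year_precip(series)

    idx = series.frame.index
    t_annual = {}
    for y in years:
        mask = idx.year == y
        if mask.any() and series.covers(dt.date(y, 1, 1), dt.date(y, 12, 31)):
            t_annual[y] = float(series.frame["t_mean"].to_numpy()[mask].mean())

    rows = []
    for s in seasons:
        y = s.season
        row: dict[str, float] = {"year": y}
        if s.censored:
            row.update(
                v_per=np.nan, v_per_paper=np.nan, v_day=np.nan,
                cold_days=np.nan, harvest_doy=np.nan, p_m_veg=np.nan, p_veg=np.nan,
            )
        else:
            water = season_water(series, y, s.sowing_date, s.harvest_date)
            row.update(
                v_per=float(s.v_per_exact),
                v_per_paper=float(s.v_per_paper),
                v_day=float(s.v_day),
                cold_days=float(s.cold_days),
                harvest_doy=float(s.harvest_doy),
                p_m_veg=water.p_m_veg,
                p_veg=water.p_veg,
            )
        for col in ("p_ha", "p_hw", "p_hs", "share_hw"):
            row[col] = float(hydro.loc[y, col]) if y in hydro.index else np.nan
        row["p_annual"] = float(p_annual[y]) if y in p_annual.index else np.nan
        row["t_mean_annual"] = t_annual.get(y, np.nan)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("year")
    return frame[METRICS]


def run_slot(
    config: SyntheticWeatherConfig,
    slot: SlotDefinition,
    params: CropParameters | None = None,
) -> tuple[pd.DataFrame, SlotSummary]:
    """Generate a slot's weather and summarise it.

    Weather is generated from the year before the slot (to cover the first
    sowing and the first hydrological year) through the slot's last year.
    Returns the per-year table and its :class:`SlotSummary`.
    """
    series = generate_weather(config, slot.start_year - 1, slot.end_year)
    table = per_year_metrics(series, slot.years, params)
    summary = summarize_slot(table, slot, site_id=config.site_id)
    return table, summary


def run_comparison(
    config_ref: SyntheticWeatherConfig,
    config_fut: SyntheticWeatherConfig,
    slot_ref: SlotDefinition,
    slot_fut: SlotDefinition,
    params: CropParameters | None = None,
) -> tuple[SlotSummary, SlotSummary, SlotDelta]:
    """Run two scenario slots for one site and compare them."""
    _, sum_ref = run_slot(config_ref, slot_ref, params)
    _, sum_fut = run_slot(config_fut, slot_fut, params)
    return sum_ref, sum_fut, compare_slots(sum_ref, sum_fut)
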