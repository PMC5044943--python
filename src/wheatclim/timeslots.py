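"""30-year time-slot aggregation and between-slot comparison.

Climate-impact statements here are differences between two 30-year
windows: a reference slot (1981–2010) and a future slot (2041–2070).
Per-year metrics (precipitation totals, winter share, growing-period
length, vegetation/cold days, harvest day of year, P_m-veg) are averaged
within each slot — censored seasons excluded, never imputed — and the
deltas between slots are reported in the units practitioners quote:
percentage points of winter share, days of growing period, weeks of
harvest advance, percent change in cold days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenology import round_half_away

__all__ = [
    "SlotDefinition",
    "MetricStat",
    "SlotSummary",
    "SlotDelta",
    "REFERENCE_SLOT",
    "FUTURE_SLOT",
    "slot_mean_sd",
    "summarize_slot",
    "compare_slots",
    "percent_change",
    "share_shift_pp",
    "harvest_advance_weeks",
]


@dataclass(frozen=True)
class SlotDefinition:
    """A labelled analysis window of consecutive years."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def __len__(self) -> int:
        return self.end_year - self.start_year + 1


#: the two 30-year slots of the study design
REFERENCE_SLOT = SlotDefinition("SCEN", 1981, 2010)
FUTURE_SLOT = SlotDefinition("FUTURE", 2041, 2070)


@dataclass(frozen=True)
class MetricStat:
    """Mean/SD of one metric over a slot, with exclusion bookkeeping."""

    mean: float
    sd: float | None  # None: undefined (fewer than 2 values)
    n: int
    n_excluded: int = 0


@dataclass(frozen=True)
class SlotSummary:
    """Per-metric means and SDs of one site over one slot."""

    label: str
    site_id: str
    stats: Mapping[str, MetricStat]

    def mean(self, metric: str) -> float:
        return self.stats[metric].mean

    def sd(self, metric: str) -> float | None:
        return self.stats[metric].sd

    def to_rows(self) -> list[dict]:
        """Long-format rows (site, slot, metric, mean, sd, n, n_excluded)."""
        return [
            {
                "site": self.site_id,
                "slot": self.label,
                "metric": m,
                "mean": s.mean,
                "sd": s.sd,
                "n": s.n,
                "n_excluded": s.n_excluded,
            }
            for m, s in self.stats.items()
        ]


@dataclass(frozen=True)
class SlotDelta:
    """Between-slot changes (future minus reference) for one site.

    ``deltas`` holds the raw mean difference per metric; the named fields
    express the headline quantities in reporting units.  The winter-share
    shift follows the convention of differencing two-decimal rounded
    shares (the unrounded shift is kept alongside).
    """

    site_id: str
    label_a: str
    label_b: str
    deltas: Mapping[str, float]
    share_shift_pp: float | None = None
    share_shift_pp_unrounded: float | None = None
    v_per_change_days: float | None = None
    harvest_advance_days: float | None = None
    harvest_advance_weeks: int | None = None
    cold_days_percent_change: float | None = None
    p_m_veg_change_mm: float | None = None


def slot_mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample SD (n−1 denominator) of yearly values.

    A single value yields an undefined SD (``None``); an empty input is an
    error.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd


def summarize_slot(
    per_year: pd.DataFrame,
    slot: SlotDefinition,
    *,
    site_id: str = "",
    metrics: Sequence[str] | None = None,
) -> SlotSummary:
    """Aggregate per-year metrics over a slot.

    ``per_year`` is indexed by year with one column per metric; NaN cells
    mark censored/undefined years and are excluded (counted per metric).
    Missing slot years are an error listing them.
    """
    missing = sorted(set(slot.years) - set(per_year.index))
    if missing:
        raise ValueError(f"slot {slot.label}: years missing from records: {missing}")
    sub = per_year.loc[list(slot.years)]
    if metrics is None:
        metrics = [c for c in sub.columns if pd.api.types.is_numeric_dtype(sub[c])]
    stats: dict[str, MetricStat] = {}
    for m in metrics:
        col = sub[m].astype(float)
        valid = col.dropna()
        mean, sd = slot_mean_sd(valid.to_numpy())
        stats[m] = MetricStat(
            mean=mean, sd=sd, n=len(valid), n_excluded=len(col) - len(valid)
        )
    return SlotSummary(label=slot.label, site_id=site_id, stats=stats)


def percent_change(old: float, new: float) -> float | None:
    """Relative change in percent; undefined (``None``) for a zero baseline."""
    if old == 0:
        return None
    return 100.0 * (new - old) / old


def share_shift_pp(share_a: float, share_b: float, *, rounded: bool = True) -> float:
    """Winter-share shift in percentage points.

    By reporting convention the shares are first rounded to two decimals
    (so 0.47 → 0.54 is exactly +7 pp); pass ``rounded=False`` for the
    full-precision shift.
    """
    if rounded:
        share_a, share_b = round(share_a, 2), round(share_b, 2)
    return round((share_b - share_a) * 100.0, 10)


def harvest_advance_weeks(advance_days: float) -> int:
    """Harvest advance in whole weeks, rounded half away from zero."""
    return round_half_away(advance_days / 7.0)


def compare_slots(a: SlotSummary, b: SlotSummary) -> SlotDelta:
    """Between-slot deltas, future (b) minus reference (a).

    Both summaries must describe the same site and metric set.  Headline
    fields are populated for whichever of the standard metrics
    (``share_hw``, ``v_per``, ``harvest_doy``, ``cold_days``, ``p_m_veg``)
    are present.
    """
    if a.site_id != b.site_id:
        raise ValueError(f"site mismatch: {a.site_id!r} vs {b.site_id!r}")
    if set(a.stats) != set(b.stats):
        raise ValueError(
            f"metric sets differ: {sorted(set(a.stats) ^ set(b.stats))}"
        )
    deltas = {m: b.mean(m) - a.mean(m) for m in a.stats}

    kw: dict[str, float | int | None] = {}
    if "share_hw" in deltas:
        kw["share_shift_pp"] = share_shift_pp(a.mean("share_hw"), b.mean("share_hw"))
        kw["share_shift_pp_unrounded"] = share_shift_pp(
            a.mean("share_hw"), b.mean("share_hw"), rounded=False
        )
    if "v_per" in deltas:
        kw["v_per_change_days"] = deltas["v_per"]
    if "harvest_doy" in deltas:
        adv = -deltas["harvest_doy"]
        kw["harvest_advance_days"] = adv
        kw["harvest_advance_weeks"] = harvest_advance_weeks(adv)
    if "cold_days" in deltas:
        kw["cold_days_percent_change"] = percent_change(
            a.mean("cold_days"), b.mean("cold_days")
        )
    if "p_m_veg" in deltas:
        kw["p_m_veg_change_mm"] = deltas["p_m_veg"]

    return SlotDelta(
        site_id=a.site_id, label_a=a.label, label_b=b.label, deltas=deltas, **kw
    )
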