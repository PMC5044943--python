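"""Daily weather series: container, validation, and delimited-text I/O.

The central data structure of the package is :class:`WeatherSeries`, a thin
wrapper around a :class:`pandas.DataFrame` holding one row per calendar day
with a mean air temperature (°C) and a precipitation total (mm).  Every
downstream stage — phenology, hydrological-year accounting, time-slot
comparison — consumes this container.

Dates are true calendar dates (leap-aware ``DatetimeIndex``), never
day-of-year integers, so February 29 is handled uniformly everywhere.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyRecord",
    "WeatherSeries",
    "ColumnMapping",
    "ValidationIssue",
    "WeatherConfigError",
    "WeatherInputError",
    "read_weather_csv",
    "validate_series",
    "fill_gaps",
    "write_weather_csv",
    "write_table",
    "read_table",
]


class WeatherConfigError(ValueError):
    """A column mapping or configuration value cannot be applied."""


class WeatherInputError(ValueError):
    """The input data violate a structural invariant (gap, duplicate, range)."""


@dataclass(frozen=True)
class DailyRecord:
    """One day of weather: calendar date, mean temperature (°C), precipitation (mm)."""

    date: dt.date
    t_mean: float
    prec: float


@dataclass(frozen=True)
class ColumnMapping:
    """Maps file columns onto the internal (date, t_mean, prec) schema.

    Defaults follow the package's native export format
    (``date,t_mean_c,prec_mm`` with an ISO-8601 date column); station
    exports with other headers are adapted by overriding the names, not by
    editing files.
    """

    date: str = "date"
    t_mean: str = "t_mean_c"
    prec: str = "prec_mm"
    delimiter: str = ","
    date_format: str | None = None  # None -> ISO-8601
    site_id: str | None = None


@dataclass(frozen=True)
class ValidationIssue:
    """A single validation finding, tied to the date on which it occurred."""

    date: dt.date | None
    rule: str
    message: str
    severity: str = "error"  # "error" | "info"


class WeatherSeries:
    """An ordered, gap-free daily weather series for one site.

    Parameters
    ----------
    site_id:
        Short text label for the station/region (e.g. ``"DH"``, ``"OS"``).
    frame:
        DataFrame with a ``DatetimeIndex`` (daily) and columns ``t_mean``
        (°C) and ``prec`` (mm).  Rows are sorted by date on construction.
    validate:
        When true (default) structural invariants are enforced immediately:
        strictly increasing dates with a step of exactly one day, finite
        temperatures, non-negative precipitation.
    """

    def __init__(
        self,
        site_id: str,
        frame: pd.DataFrame,
        *,
        validate: bool = True,
        filled_dates: Sequence[dt.date] = (),
    ) -> None:
        frame = frame.copy()
        if not isinstance(frame.index, pd.DatetimeIndex):
            frame.index = pd.DatetimeIndex(frame.index)
        frame.index.name = "date"
        frame = frame.sort_index()
        missing = {"t_mean", "prec"} - set(frame.columns)
        if missing:
            raise WeatherConfigError(f"frame lacks required columns: {sorted(missing)}")
        frame["t_mean"] = frame["t_mean"].astype(float)
        frame["prec"] = frame["prec"].astype(float)
        self.site_id = site_id
        self.frame = frame
        self.filled_dates: tuple[dt.date, ...] = tuple(filled_dates)
        if validate:
            issues = validate_series(self)
            errors = [i for i in issues if i.severity == "error"]
            if errors:
                first = errors[0]
                raise WeatherInputError(
                    f"invalid weather series ({len(errors)} problem(s)); first: "
                    f"{first.rule} on {first.date}: {first.message}"
                )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_records(
        cls, site_id: str, records: Iterable[DailyRecord], *, validate: bool = True
    ) -> "WeatherSeries":
        recs = list(records)
        frame = pd.DataFrame(
            {
                "t_mean": [r.t_mean for r in recs],
                "prec": [r.prec for r in recs],
            },
            index=pd.DatetimeIndex([pd.Timestamp(r.date) for r in recs]),
        )
        return cls(site_id, frame, validate=validate)

    @classmethod
    def from_arrays(
        cls,
        site_id: str,
        dates: Sequence[dt.date] | pd.DatetimeIndex,
        t_mean: Sequence[float],
        prec: Sequence[float],
        *,
        validate: bool = True,
    ) -> "WeatherSeries":
        frame = pd.DataFrame(
            {"t_mean": np.asarray(t_mean, float), "prec": np.asarray(prec, float)},
            index=pd.DatetimeIndex(dates),
        )
        return cls(site_id, frame, validate=validate)

    # -- accessors -----------------------------------------------------------

    @property
    def records(self) -> list[DailyRecord]:
        return [
            DailyRecord(ts.date(), float(row.t_mean), float(row.prec))
            for ts, row in self.frame.iterrows()
        ]

    @property
    def start(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.frame.index[-1].date()

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[DailyRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeatherSeries):
            return NotImplemented
        return self.site_id == other.site_id and self.frame.equals(other.frame)

    def covers(self, start: dt.date, end: dt.date) -> bool:
        """True if every day of [start, end] is present."""
        return self.start <= start and self.end >= end

    def window(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        """Endpoint-inclusive daily slice; raises if the window is not covered."""
        if not self.covers(start, end):
            raise WeatherInputError(
                f"series {self.site_id} covers {self.start}..{self.end}, "
                f"requested {start}..{end}"
            )
        return self.frame.loc[pd.Timestamp(start) : pd.Timestamp(end)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeatherSeries(site_id={self.site_id!r}, n={len(self)}, "
            f"{self.start}..{self.end})"
        )


def validate_series(series: WeatherSeries) -> list[ValidationIssue]:
    """Check every series invariant and report all violations.

    Returns an empty list iff the series is fully valid: strictly
    increasing dates with no duplicate and no missing calendar day, finite
    temperatures, and non-negative finite precipitation.  Days produced by
    an opt-in gap fill are reported as ``severity="info"`` entries so the
    interpolation is never silent.
    """
    issues: list[ValidationIssue] = []
    idx = series.frame.index
    if len(idx) == 0:
        issues.append(ValidationIssue(None, "empty", "series contains no records"))
        return issues

    dup = idx[idx.duplicated()]
    for ts in dup:
        issues.append(ValidationIssue(ts.date(), "duplicate-date", "date occurs twice"))

    if not dup.size:
        full = pd.date_range(idx[0], idx[-1], freq="D")
        missing = full.difference(idx)
        for ts in missing:
            issues.append(
                ValidationIssue(ts.date(), "gap", "calendar day missing from series")
            )

    t = series.frame["t_mean"]
    for ts in t.index[~np.isfinite(t.to_numpy())]:
        issues.append(
            ValidationIssue(ts.date(), "non-finite-temperature", "t_mean is NaN/inf")
        )
    p = series.frame["prec"]
    p_arr = p.to_numpy()
    bad_p = ~np.isfinite(p_arr) | (p_arr < 0)
    for ts in p.index[bad_p]:
        issues.append(
            ValidationIssue(
                ts.date(), "invalid-precipitation", "prec is negative or non-finite"
            )
        )

    for d in series.filled_dates:
        issues.append(
            ValidationIssue(
                d, "gap-filled", "value linearly interpolated over a short gap", "info"
            )
        )
    return issues


def fill_gaps(
    site_id: str, frame: pd.DataFrame, max_gap: int = 3
) -> tuple[pd.DataFrame, list[dt.date]]:
    """Linearly interpolate gaps of at most ``max_gap`` consecutive days.

    Longer gaps remain (and will fail validation).  Returns the filled
    frame and the list of inserted dates.
    """
    idx = frame.index
    full = pd.date_range(idx[0], idx[-1], freq="D")
    missing = full.difference(idx)
    if missing.empty:
        return frame, []
    # identify runs of consecutive missing days
    fillable: list[pd.Timestamp] = []
    run: list[pd.Timestamp] = []
    prev = None
    for ts in list(missing) + [None]:
        if prev is not None and ts is not None and (ts - prev).days == 1:
            run.append(ts)
        else:
            if run and len(run) <= max_gap:
                fillable.extend(run)
            run = [ts] if ts is not None else []
        prev = ts
    if not fillable:
        return frame, []
    keep = idx.union(pd.DatetimeIndex(fillable))
    out = frame.reindex(keep).interpolate(method="time", limit_area="inside")
    return out, [ts.date() for ts in fillable]


def read_weather_csv(
    path: str | Path,
    dialect: ColumnMapping | Mapping[str, str] | None = None,
    *,
    gap_fill: bool = False,
    max_gap: int = 3,
) -> WeatherSeries:
    """Read a delimited daily-weather file into a validated :class:`WeatherSeries`.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    dialect:
        A :class:`ColumnMapping` (or plain dict of its fields) naming the
        date/temperature/precipitation columns, the delimiter, and
        optionally a site id.  Defaults to the package's native
        ``date,t_mean_c,prec_mm`` layout with ISO-8601 dates.
    gap_fill:
        Opt in to linear interpolation of gaps of at most ``max_gap`` days;
        filled days are flagged by :func:`validate_series`.  Off by default:
        missing days are a hard error, because degree-day sums silently
        shrink with gaps.
    """
    if dialect is None:
        dialect = ColumnMapping()
    elif isinstance(dialect, Mapping):
        dialect = ColumnMapping(**dict(dialect))

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    for col in (dialect.date, dialect.t_mean, dialect.prec):
        if col not in raw.columns:
            raise WeatherConfigError(
                f"column {col!r} not found in {path.name}; have {list(raw.columns)}"
            )

    dates = pd.to_datetime(
        raw[dialect.date], format=dialect.date_format, errors="coerce"
    )
    bad = dates.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise WeatherInputError(
            f"unparseable date {raw[dialect.date][bad.idxmax()]!r} "
            f"at line {line} of {path.name}"
        )
    dup_mask = dates.duplicated()
    if dup_mask.any():
        raise WeatherInputError(
            f"duplicate date {dates[dup_mask.idxmax()].date()} in {path.name}"
        )

    frame = pd.DataFrame(
        {
            "t_mean": pd.to_numeric(raw[dialect.t_mean], errors="coerce").to_numpy(),
            "prec": pd.to_numeric(raw[dialect.prec], errors="coerce").to_numpy(),
        },
        index=pd.DatetimeIndex(dates),
    ).sort_index()

    filled: list[dt.date] = []
    if gap_fill:
        frame, filled = fill_gaps(dialect.site_id or path.stem, frame, max_gap=max_gap)

    site_id = dialect.site_id or path.stem
    return WeatherSeries(site_id, frame, filled_dates=filled)


def write_weather_csv(series: WeatherSeries, path: str | Path) -> None:
    """Write a series in the native ``date,t_mean_c,prec_mm`` layout."""
    out = series.frame.rename(columns={"t_mean": "t_mean_c", "prec": "prec_mm"})
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


def write_table(
    rows: Sequence[Mapping | object],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write keyed records (dicts or dataclasses) as a header-ed CSV.

    All rows must share one key set.  ``columns`` fixes the header order and
    lets an empty row list still produce a header-only file; values
    round-trip through :func:`read_table`.
    """
    dicts = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in rows
    ]
    if dicts:
        keys = list(dicts[0].keys())
        for d in dicts[1:]:
            if set(d.keys()) != set(keys):
                raise WeatherConfigError("write_table requires homogeneous keys")
        if columns is None:
            columns = keys
    frame = pd.DataFrame(dicts, columns=list(columns) if columns is not None else None)
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path)
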