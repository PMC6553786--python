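"""Data model and I/O for dated event series.

An event calendar is an ordered list of calendar dates, one per event,
with multiplicity (several events may fall on the same day).  All
downstream analyses work on the derived daily count series, whose
cumulative sum is the counting process N(t).

Day indexing is 1-based over the inclusive observation window
[origin, horizon]: day index = (date - origin) + 1.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EventCalendar",
    "DailyCountSeries",
    "InterArrivalSeries",
    "BinarySeries",
    "GroupedSamples",
    "parse_event_dates",
    "to_daily_counts",
    "inter_arrival_times",
    "split_at",
    "group_counts",
]

GROUPING_SCHEMES = ("year", "trimester", "month", "weekday")


@dataclass(frozen=True)
class EventCalendar:
    """Ordered event dates (duplicates allowed) over a fixed window."""

    dates: tuple[_dt.date, ...]
    origin: _dt.date
    horizon: _dt.date

    def __post_init__(self) -> None:
        if self.horizon < self.origin:
            raise ValueError("horizon precedes origin")
        srt = tuple(sorted(self.dates))
        object.__setattr__(self, "dates", srt)
        for d in (srt[0], srt[-1]) if srt else ():
            if not (self.origin <= d <= self.horizon):
                raise ValueError(f"event date {d} outside window "
                                 f"[{self.origin}, {self.horizon}]")

    @property
    def count(self) -> int:
        return len(self.dates)

    @property
    def n_days(self) -> int:
        return (self.horizon - self.origin).days + 1

    def day_indices(self) -> np.ndarray:
        """1-based day index of every event, with multiplicity."""
        o = self.origin
        return np.array([(d - o).days + 1 for d in self.dates], dtype=np.int64)


@dataclass(frozen=True)
class DailyCountSeries:
    """Non-negative integer event counts per day t = 1..T."""

    counts: np.ndarray
    origin_date: _dt.date | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def T(self) -> int:
        return int(self.counts.shape[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def counting_process(self) -> np.ndarray:
        """N(t) = cumulative number of events up to and including day t."""
        return np.cumsum(self.counts)

    def event_days(self) -> np.ndarray:
        """1-based day index of every event, with multiplicity."""
        return np.repeat(np.arange(1, self.T + 1), self.counts)

    def binarize(self) -> "BinarySeries":
        return BinarySeries(bits=(self.counts > 0).astype(np.int64))

    def summary(self) -> dict:
        return {
            "T": self.T,
            "total_events": self.total,
            "rate": self.total / self.T if self.T else 0.0,
            "origin_date": self.origin_date.isoformat() if self.origin_date else None,
        }


@dataclass(frozen=True)
class InterArrivalSeries:
    """Whole-day gaps between successive events; same-day pairs give 0."""

    gaps: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gaps, dtype=np.int64)
        if (g < 0).any():
            raise ValueError("gaps must be non-negative")
        object.__setattr__(self, "gaps", g)

    @property
    def n(self) -> int:
        return int(self.gaps.shape[0])


@dataclass(frozen=True)
class BinarySeries:
    """0/1 per day: 1 iff at least one event occurred that day."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.int64)
        if not np.isin(b, (0, 1)).all():
            raise ValueError("bits must be 0 or 1")
        object.__setattr__(self, "bits", b)

    @property
    def T(self) -> int:
        return int(self.bits.shape[0])


@dataclass(frozen=True)
class GroupedSamples:
    """Daily counts partitioned by a calendar attribute."""

    scheme: str
    groups: Mapping[str, np.ndarray] = field(default_factory=dict)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}


def parse_event_dates(
    source: str | IO[str],
    window_start: _dt.date | str | None = None,
    window_end: _dt.date | str | None = None,
) -> EventCalendar:
    """Read an event calendar from a CSV with a ``date`` column.

    Dates must be ISO-8601 (YYYY-MM-DD); extra columns are ignored.  The
    observation window defaults to [min date, max date] unless overridden.
    """
    df = pd.read_csv(source)
    if "date" not in df.columns:
        raise ValueError("CSV must contain a 'date' column")
    if df.empty:
        raise ValueError("empty event list")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        # pin the offending row for the error message
        for i, raw in enumerate(df["date"]):
            try:
                pd.to_datetime(raw, format="ISO8601")
            except (ValueError, TypeError):
                raise ValueError(f"malformed date {raw!r} at row {i}") from exc
        raise
    pydates = tuple(sorted(d.date() for d in dates))
    origin = _as_date(window_start) if window_start else pydates[0]
    horizon = _as_date(window_end) if window_end else pydates[-1]
    return EventCalendar(dates=pydates, origin=origin, horizon=horizon)


def _as_date(d: _dt.date | str) -> _dt.date:
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(d)


def calendar_from_day_indices(days: Iterable[int], T: int,
                              origin: _dt.date | None = None) -> EventCalendar:
    """Build a calendar from 1-based day indices over a window of T days."""
    origin = origin or _dt.date(2000, 1, 1)
    dates = tuple(origin + _dt.timedelta(days=int(d) - 1) for d in days)
    return EventCalendar(dates=dates, origin=origin,
                         horizon=origin + _dt.timedelta(days=T - 1))


def to_daily_counts(cal: EventCalendar) -> DailyCountSeries:
    """Discretize a calendar into per-day event counts over its window."""
    counts = np.zeros(cal.n_days, dtype=np.int64)
    if cal.count:
        idx, mult = np.unique(cal.day_indices(), return_counts=True)
        counts[idx - 1] = mult
    return DailyCountSeries(counts=counts, origin_date=cal.origin)


def inter_arrival_times(s: DailyCountSeries) -> InterArrivalSeries:
    """Whole-day gaps T_k between successive events (same day -> gap 0)."""
    if s.total < 2:
        raise ValueError("need at least 2 events for inter-arrival times")
    return InterArrivalSeries(gaps=np.diff(s.event_days()))


def split_at(s: DailyCountSeries, day: int) -> tuple[DailyCountSeries, DailyCountSeries]:
    """Split the series after ``day``: the first part is days 1..day.

    The split day itself belongs to the first part, so a change-point at
    day tau yields segments of lengths tau and T - tau.
    """
    if not 1 <= day < s.T:
        raise ValueError(f"split day {day} out of range 1..{s.T - 1}")
    second_origin = None
    if s.origin_date is not None:
        second_origin = s.origin_date + _dt.timedelta(days=day)
    return (
        DailyCountSeries(counts=s.counts[:day], origin_date=s.origin_date),
        DailyCountSeries(counts=s.counts[day:], origin_date=second_origin),
    )


def group_counts(s: DailyCountSeries, scheme: str) -> GroupedSamples:
    """Partition the daily counts by year, trimester, month or weekday."""
    if scheme not in GROUPING_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {GROUPING_SCHEMES}")
    if s.origin_date is None:
        raise ValueError("origin_date required for calendar grouping")
    idx = pd.date_range(start=s.origin_date, periods=s.T, freq="D")
    if scheme == "year":
        labels = idx.year.astype(str)
    elif scheme == "month":
        labels = idx.strftime("%b")
    elif scheme == "weekday":
        labels = idx.strftime("%a")
    else:  # trimester = calendar quarter
        labels = "Q" + idx.quarter.astype(str)
    frame = pd.DataFrame({"label": labels, "count": s.counts})
    groups = {str(k): g["count"].to_numpy()
              for k, g in frame.groupby("label", sort=True)}
    return GroupedSamples(scheme=scheme, groups=groups)
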