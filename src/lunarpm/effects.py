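"""Instantaneous-effect statistics and the city response classification.

The firework signature is an hours-scale burst: concentrated discharge in
the 00:00-04:00 window of Lunar New Year's Day drives the national hourly
mean to its yearly maximum, typically at 02:00.  This module computes the
national hourly mean, per-day maxima with their hour-of-day, the
peak-to-baseline ratio of an event day against its flanking days, and a
three-category classification of each city's response within a celebration
period:

significant
    the city's maximum concentration over the celebration period falls in
    the 00:00-04:00 window of New Year's Day;
obvious
    it does not, but the New-Year-night increase (value at 04:00 minus
    value at 00:00) and increase rate (increase divided by the 00:00 value)
    are both strictly the largest among the celebration days considered;
weak
    neither condition holds.

Days around the Lantern Festival (lunar days 14-16) close the celebrations
with their own displays and are excluded from the classification.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import StationSeries
from .periods import PeriodDivision

__all__ = [
    "DailyMaxRecord",
    "ResponseLabel",
    "national_hourly_mean",
    "city_hourly_series",
    "daily_max_series",
    "peak_ratio",
    "classify_response",
]

#: discharge window on New Year's Day, inclusive hour bounds
DISCHARGE_WINDOW = (0, 4)


@dataclass(frozen=True)
class DailyMaxRecord:
    date: dt.date
    max_value: float  # NaN when the day is fully missing
    max_hour: int | None  # earliest hour attaining the maximum; None if missing

    @property
    def missing(self) -> bool:
        return self.max_hour is None


@dataclass
class ResponseLabel:
    city: str
    cycle_tag: int
    category: str  # significant | obvious | weak
    evidence: dict = field(default_factory=dict)


def national_hourly_mean(series: StationSeries) -> pd.Series:
    """Unweighted mean over all stations reporting each hour."""
    if series.frame.empty or not series.station_ids:
        raise ValueError("empty station series")
    return series.frame.mean(axis=1, skipna=True)


def city_hourly_series(series: StationSeries, station_ids) -> pd.Series:
    """A city's hourly series as the unweighted mean of its stations."""
    return series.frame[list(station_ids)].mean(axis=1, skipna=True)


def daily_max_series(national: pd.Series) -> list[DailyMaxRecord]:
    """Per calendar day: the maximum hourly value and its (earliest) hour."""
    if national.empty:
        raise ValueError("empty hourly series")
    records = []
    for day, block in national.groupby(national.index.normalize()):
        clean = block.dropna()
        if clean.empty:
            records.append(DailyMaxRecord(day.date(), float("nan"), None))
            continue
        at = clean.idxmax()  # earliest timestamp on ties
        records.append(DailyMaxRecord(day.date(), float(clean.loc[at]), int(at.hour)))
    return records


def peak_ratio(
    daily_max: list[DailyMaxRecord], event_date: dt.date, window: int = 1
) -> float:
    """Event-day maximum as a percentage of the flanking days' mean maximum.

    The baseline pools the daily maxima of the ``window`` days on each side
    of ``event_date`` (default one day each side).
    """
    by_date = {r.date: r for r in daily_max}
    if event_date not in by_date or by_date[event_date].missing:
        raise ValueError(f"no daily maximum for event day {event_date}")
    neighbors = []
    for off in range(1, window + 1):
        for d in (event_date - dt.timedelta(days=off),
                  event_date + dt.timedelta(days=off)):
            rec = by_date.get(d)
            if rec is None or rec.missing:
                raise ValueError(f"missing flanking day {d}")
            neighbors.append(rec.max_value)
    return 100.0 * by_date[event_date].max_value / float(np.mean(neighbors))


# ---------------------------------------------------------------------------
# response classification


def _considered_days(division: PeriodDivision) -> list[dt.date]:
    """Celebration days entering the classification (Lantern period excluded)."""
    win = division.celebration
    lantern = {win.lantern_festival - dt.timedelta(days=1),
               win.lantern_festival,
               win.lantern_festival + dt.timedelta(days=1)}
    day = win.start_date
    out = []
    while day <= win.end_date:
        if day not in lantern:
            out.append(day)
        day += dt.timedelta(days=1)
    return out


def _window_increase(city: pd.Series, day: dt.date) -> tuple[float, float]:
    """(increase, increase rate) over the 00:00-04:00 window of ``day``."""
    t0 = pd.Timestamp(day) + pd.Timedelta(hours=DISCHARGE_WINDOW[0])
    t1 = pd.Timestamp(day) + pd.Timedelta(hours=DISCHARGE_WINDOW[1])
    v0 = city.get(t0, np.nan)
    v1 = city.get(t1, np.nan)
    inc = v1 - v0
    rate = inc / v0 if v0 and np.isfinite(v0) and v0 > 0 else np.nan
    return float(inc), float(rate)


def classify_response(
    city_series: pd.Series, division: PeriodDivision, city: str = ""
) -> ResponseLabel:
    """Categorise one city's PM2.5 response for one celebration period."""
    days = _considered_days(division)
    win = division.celebration
    ny = win.new_year_day

    sel = city_series.loc[
        city_series.index.normalize().isin(pd.to_datetime(days))
    ].dropna()
    if sel.empty:
        raise ValueError("city series has no data in the celebration period")

    lo, hi = DISCHARGE_WINDOW
    ny_window = city_series.loc[
        pd.Timestamp(ny) + pd.Timedelta(hours=lo):
        pd.Timestamp(ny) + pd.Timedelta(hours=hi)
    ]
    if ny_window.isna().any() or len(ny_window) < hi - lo + 1:
        warnings.warn(
            f"incomplete 00:00-04:00 window on New Year's Day for {city or 'city'}; "
            "classification uses available hours",
            stacklevel=2,
        )

    at_max = sel.idxmax()  # earliest on ties
    evidence: dict = {
        "window_max": float(sel.loc[at_max]),
        "window_max_time": at_max.isoformat(),
        "days_considered": len(days),
    }

    if at_max.date() == ny and lo <= at_max.hour <= hi:
        return ResponseLabel(city, division.cycle_tag, "significant", evidence)

    incs = {d: _window_increase(city_series, d) for d in days}
    ny_inc, ny_rate = incs[ny]
    evidence["ny_increase"] = ny_inc
    evidence["ny_increase_rate"] = ny_rate
    evidence["daily_increases"] = {
        d.isoformat(): {"increase": i, "rate": r} for d, (i, r) in incs.items()
    }
    others = [(i, r) for d, (i, r) in incs.items() if d != ny]
    inc_top = np.isfinite(ny_inc) and all(
        not np.isfinite(i) or ny_inc > i for i, _ in others
    )
    rate_top = np.isfinite(ny_rate) and all(
        not np.isfinite(r) or ny_rate > r for _, r in others
    )
    if inc_top and rate_top:
        return ResponseLabel(city, division.cycle_tag, "obvious", evidence)
    return ResponseLabel(city, division.cycle_tag, "weak", evidence)
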