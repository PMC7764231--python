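"""Lunar-anchored 17-day time division.

The Chinese New Year celebration window spans 17 days (denoted dt in the
notation below): New Year's Eve, New Year's Day, the first lunar month up to
the Lantern Festival (lunar day 15), and the day after it.  Anchored on that
window, each lunar cycle (one celebration window up to, but excluding, the
next) is tiled with twenty-one contiguous labelled periods:

    celebration, post-1 ... post-10, pre-10, pre-9 ... pre-1

in chronological order.  All periods are exactly 17 days long except
``pre-10``, which absorbs the residual days of the cycle (lunar years are
shorter than solar years, so the residual is typically around two weeks and
falls in summer).

Anchor dates (the Gregorian date of each Lunar New Year's Day) are supplied
as data; no astronomical computation is performed.  ``DEFAULT_ANCHORS``
carries the 2013-2016 festival dates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

__all__ = [
    "CELEBRATION_DAYS",
    "DEFAULT_ANCHORS",
    "CelebrationWindow",
    "PeriodDivision",
    "celebration_window",
    "divide_cycle",
    "assign_period",
    "build_divisions",
    "period_labels",
]

#: length of the celebration window, in days
CELEBRATION_DAYS = 17

#: Gregorian dates of Lunar New Year's Day for the station-record years
DEFAULT_ANCHORS = (
    dt.date(2013, 2, 10),
    dt.date(2014, 1, 31),
    dt.date(2015, 2, 19),
    dt.date(2016, 2, 8),
)

_ONE_DAY = dt.timedelta(days=1)


def period_labels() -> list[str]:
    """The 21 period labels in chronological (cycle) order."""
    return (
        ["celebration"]
        + [f"post-{i}" for i in range(1, 11)]
        + [f"pre-{i}" for i in range(10, 0, -1)]
    )


@dataclass(frozen=True)
class CelebrationWindow:
    """The 17-day festival window for one lunar year.

    ``start_date`` is New Year's Eve and ``end_date`` the day after the
    Lantern Festival; New Year's Day is ``start_date + 1``.
    """

    year_tag: int
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if (self.end_date - self.start_date).days + 1 != CELEBRATION_DAYS:
            raise ValueError("celebration window must span exactly 17 days")

    @property
    def new_year_day(self) -> dt.date:
        return self.start_date + _ONE_DAY

    @property
    def lantern_festival(self) -> dt.date:
        """Lunar day 15 (two days before the window closes)."""
        return self.end_date - _ONE_DAY

    def __contains__(self, day: dt.date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass
class PeriodDivision:
    """21 labelled, contiguous periods exactly tiling one lunar cycle."""

    cycle_tag: int
    periods: list[tuple[str, dt.date, dt.date]]

    @property
    def start(self) -> dt.date:
        return self.periods[0][1]

    @property
    def end(self) -> dt.date:
        return self.periods[-1][2]

    def window(self, label: str) -> tuple[dt.date, dt.date]:
        for lab, s, e in self.periods:
            if lab == label:
                return s, e
        raise KeyError(label)

    @property
    def celebration(self) -> CelebrationWindow:
        s, e = self.window("celebration")
        return CelebrationWindow(self.cycle_tag, s, e)


def celebration_window(new_year_day: dt.date) -> CelebrationWindow:
    """Build the 17-day window [Eve, day after the Lantern Festival]."""
    return CelebrationWindow(
        year_tag=new_year_day.year,
        start_date=new_year_day - _ONE_DAY,
        end_date=new_year_day + dt.timedelta(days=15),
    )


def divide_cycle(
    this_window: CelebrationWindow, next_window: CelebrationWindow
) -> PeriodDivision:
    """Tile the cycle [this_window.start, next_window.start - 1] into 21 periods.

    Ten 17-day post-celebration blocks follow the celebration window; nine
    17-day pre-celebration blocks are counted back from the next window's
    start; whatever remains in between becomes the residual ``pre-10``.
    """
    if next_window.start_date <= this_window.end_date:
        raise ValueError("next celebration window must start after this one ends")
    step = dt.timedelta(days=CELEBRATION_DAYS)
    gap = (next_window.start_date - this_window.end_date).days - 1
    needed = 19 * CELEBRATION_DAYS
    if gap < needed:
        raise ValueError(
            f"cycle too short: {needed - gap} more days needed to fit "
            f"ten post- and nine pre-celebration 17-day blocks"
        )

    periods: list[tuple[str, dt.date, dt.date]] = [
        ("celebration", this_window.start_date, this_window.end_date)
    ]
    cursor = this_window.end_date + _ONE_DAY
    for i in range(1, 11):
        periods.append((f"post-{i}", cursor, cursor + step - _ONE_DAY))
        cursor = cursor + step
    # pre-blocks counted back from the next window
    pre_starts = [next_window.start_date - k * step for k in range(9, 0, -1)]
    residual_end = pre_starts[0] - _ONE_DAY
    periods.append(("pre-10", cursor, residual_end))
    for i, s in zip(range(9, 0, -1), pre_starts):
        periods.append((f"pre-{i}", s, s + step - _ONE_DAY))
    return PeriodDivision(cycle_tag=this_window.year_tag, periods=periods)


def assign_period(day: dt.date, division: PeriodDivision) -> str:
    """Label of the period containing ``day`` (total over the cycle)."""
    if not division.start <= day <= division.end:
        raise ValueError(f"{day} outside cycle [{division.start}, {division.end}]")
    for label, s, e in division.periods:
        if s <= day <= e:
            return label
    raise AssertionError("tiling invariant violated")  # pragma: no cover


def build_divisions(anchor_dates) -> list[PeriodDivision]:
    """Divisions for every consecutive pair of New Year anchor dates."""
    anchors = sorted(anchor_dates)
    if len(anchors) < 2:
        raise ValueError("need at least two anchor dates to bound a cycle")
    windows = [celebration_window(a) for a in anchors]
    return [divide_cycle(w0, w1) for w0, w1 in zip(windows[:-1], windows[1:])]
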