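"""Firework prohibition-policy evaluation by baseline anomalies.

The normal level for a city and lunar cycle is the 34-day mean of all
hourly values in the adjacent pre-celebration (pre-1, 17 days) and
post-celebration (post-1, 17 days) periods.  Hourly anomalies over the
celebration period — value minus that scalar baseline — isolate what the
festival adds on top of the season.  Comparing the New-Year-night
(00:00-04:00) anomaly across years before and after a prohibition policy
took effect measures whether the policy curbed the discharge burst; the
full-period mean anomaly measures whether it changed the sustained level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .effects import DISCHARGE_WINDOW
from .periods import PeriodDivision

__all__ = ["baseline_34day", "celebration_anomaly", "compare_policy_years"]


def _period_slice(series: pd.Series, division: PeriodDivision, label: str) -> pd.Series:
    s, e = division.window(label)
    return series.loc[pd.Timestamp(s): pd.Timestamp(e) + pd.Timedelta(hours=23)]


def baseline_34day(city_series: pd.Series, division: PeriodDivision) -> float:
    """Mean of all hourly values in the pre-1 and post-1 periods (34 days)."""
    block = pd.concat(
        [_period_slice(city_series, division, "pre-1"),
         _period_slice(city_series, division, "post-1")]
    )
    n_present = int(block.notna().sum())
    if n_present == 0:
        raise ValueError("no data in the 34 baseline days")
    if n_present < 0.5 * 34 * 24:
        warnings.warn(
            f"baseline computed from {n_present} of {34 * 24} hours (<50% complete)",
            stacklevel=2,
        )
    return float(block.mean())


def celebration_anomaly(
    city_series: pd.Series, division: PeriodDivision
) -> pd.Series:
    """Hourly (value - baseline) over the celebration period; NaNs persist."""
    base = baseline_34day(city_series, division)
    cel = _period_slice(city_series, division, "celebration")
    return cel - base


def compare_policy_years(
    anomalies_by_year: dict[int, tuple[pd.Series, PeriodDivision]],
    policy_start_year: int,
) -> pd.DataFrame:
    """Summarise discharge-window and full-period anomalies around a policy.

    ``anomalies_by_year`` maps a cycle year to its celebration-period
    anomaly series and division.  Returns one row per year with the mean
    anomaly over 00:00-04:00 of New Year's Day (``night_anomaly``), the
    mean over the whole celebration period (``period_anomaly``), and a
    ``post_policy`` flag; the frame's ``attrs`` carry ``night_declined``
    and ``period_change`` comparing post- vs pre-policy year means.
    """
    if not anomalies_by_year:
        raise ValueError("no years to compare")
    rows = []
    for year in sorted(anomalies_by_year):
        anom, division = anomalies_by_year[year]
        ny = division.celebration.new_year_day
        lo, hi = DISCHARGE_WINDOW
        night = anom.loc[
            pd.Timestamp(ny) + pd.Timedelta(hours=lo):
            pd.Timestamp(ny) + pd.Timedelta(hours=hi)
        ]
        rows.append(
            {
                "year": year,
                "night_anomaly": float(night.mean()),
                "period_anomaly": float(anom.mean()),
                "post_policy": year >= policy_start_year,
            }
        )
    table = pd.DataFrame(rows)
    pre = table[~table["post_policy"]]
    post = table[table["post_policy"]]
    if len(pre) and len(post):
        table.attrs["night_declined"] = bool(
            post["night_anomaly"].mean() < pre["night_anomaly"].mean()
        )
        table.attrs["period_change"] = float(
            post["period_anomaly"].mean() - pre["period_anomaly"].mean()
        )
    return table
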