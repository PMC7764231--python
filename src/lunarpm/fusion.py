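"""Multi-year fusion of retrieved PM2.5 grids and period-mean statistics.

Satellite-retrieved daily PM2.5 fields are patchy (clouds, bright surfaces),
so coverage is improved by fusing all days that share a period label across
the simulated years into a single per-label mean map: a pixel of the fused
map is the mean of every non-missing contributing day, and is missing only
when no day contributes.

``period_means`` is the station-side counterpart: the unweighted mean of all
station-hours inside each labelled period, plus a per-cycle flanking
baseline (the mean of the pre-1 and post-1 period means) against which the
celebration-period level is compared.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .io_formats import GridField, StationSeries, UNITS
from .periods import PeriodDivision, assign_period

__all__ = ["fuse_periods", "period_means"]


def _find_division(day: dt.date, divisions: list[PeriodDivision]):
    for div in divisions:
        if div.start <= day <= div.end:
            return div
    return None


def fuse_periods(
    grids: list[GridField], divisions: list[PeriodDivision]
) -> dict[str, GridField]:
    """Fuse daily grids into one mean map per period label across all cycles."""
    if not grids:
        raise ValueError("no grids to fuse")
    ref = grids[0]
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for g in grids:
        if not g.same_geometry(ref):
            raise ValueError("all grids must share one geometry")
        div = _find_division(g.date, divisions)
        if div is None:
            raise ValueError(f"grid date {g.date} not covered by any cycle")
        label = assign_period(g.date, div)
        if label not in sums:
            sums[label] = np.zeros_like(ref.data)
            counts[label] = np.zeros(ref.data.shape, dtype=int)
        present = ~np.isnan(g.data)
        sums[label][present] += g.data[present]
        counts[label][present] += 1
    fused = {}
    for label, total in sums.items():
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[label] > 0, total / counts[label], np.nan)
        fld = ref.copy_with(mean, variable="PM2.5", units=UNITS["PM2.5"])
        fld.date = min(g.date for g in grids)  # representative tag only
        fused[label] = fld
    return fused


def period_means(
    series: StationSeries, divisions: list[PeriodDivision]
) -> pd.DataFrame:
    """Mean PM2.5 per (cycle, period label), with the flanking baseline.

    Returns one row per period with columns ``cycle``, ``label``, ``start``,
    ``end``, ``mean`` (mean over all stations and hours; NaN when the period
    has no observation) and, on every row of a cycle, ``flanking_mean`` =
    the equal-weight mean of that cycle's pre-1 and post-1 period means.
    """
    frame = series.frame
    dates = frame.index.normalize()
    rows = []
    for div in divisions:
        by_label = {}
        for label, s, e in div.periods:
            sel = np.asarray((dates >= pd.Timestamp(s)) & (dates <= pd.Timestamp(e)))
            block = frame.loc[sel]
            vals = block.to_numpy(dtype=float)
            mean = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
            by_label[label] = mean
            rows.append(
                {"cycle": div.cycle_tag, "label": label, "start": s, "end": e,
                 "mean": mean}
            )
        flank = np.nanmean([by_label.get("pre-1", np.nan),
                            by_label.get("post-1", np.nan)])
        for row in rows[-len(div.periods):]:
            row["flanking_mean"] = float(flank)
    return pd.DataFrame(rows)
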