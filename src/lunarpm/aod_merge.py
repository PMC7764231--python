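"""Combine same-day Terra and Aqua AOD grids into one daily field.

The two polar orbiters overpass in the morning and early afternoon, so their
daily snapshots are merged per pixel: both present -> arithmetic mean, one
present -> that value, both missing -> missing.  No quality-flag screening
is applied; inputs are assumed to be pre-gridded daily fields.
"""

from __future__ import annotations

import numpy as np

from .io_formats import GridField, UNITS

__all__ = ["merge_daily_aod"]


def merge_daily_aod(terra: GridField, aqua: GridField) -> GridField:
    """Per-pixel Terra/Aqua combination on a shared daily grid."""
    if terra.date != aqua.date:
        raise ValueError(f"date mismatch: {terra.date} vs {aqua.date}")
    if not terra.same_geometry(aqua):
        raise ValueError("Terra and Aqua grids differ in shape or extent")
    a, b = terra.data, aqua.data
    both = ~np.isnan(a) & ~np.isnan(b)
    out = np.where(np.isnan(a), b, a)  # one-sided pixels (and NaN where neither)
    out = np.where(both, 0.5 * (a + b), out)
    return terra.copy_with(out, variable="AOD", units=UNITS["AOD"])
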