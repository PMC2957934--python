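"""Season conventions for the study region.

The dry season runs May through October, the months of highest ambient
endotoxin; the wet season is November through March.  April has variable
precipitation and belongs to neither season, so season-filtered analyses
drop it entirely.
"""

from __future__ import annotations

import pandas as pd

DRY_MONTHS = frozenset({5, 6, 7, 8, 9, 10})
WET_MONTHS = frozenset({11, 12, 1, 2, 3})

SEASONS = ("dry", "wet")


def season_of(date) -> str | None:
    """Return 'dry', 'wet' or None (April) for a date-like value."""
    month = pd.Timestamp(date).month
    if month in DRY_MONTHS:
        return "dry"
    if month in WET_MONTHS:
        return "wet"
    return None


def season_mask(dates: pd.DatetimeIndex, season: str | None) -> pd.Series:
    """Boolean mask selecting dates in the given season (None = all dates)."""
    idx = pd.DatetimeIndex(dates)
    if season is None:
        return pd.Series(True, index=idx)
    if season == "dry":
        months = DRY_MONTHS
    elif season == "wet":
        months = WET_MONTHS
    else:
        raise ValueError(f"unknown season {season!r}; expected 'dry', 'wet' or None")
    return pd.Series(idx.month.isin(list(months)), index=idx)
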