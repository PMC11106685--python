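"""Monthly and seasonal bloom-area accounting for mass-flowering crops.

Each crop's planted area is spread uniformly over its inclusive bloom
window (whole months, non-wrapping), so a crop blooming April-June
contributes one third of its area to each of those months.  Summing over
crops gives the area of crop in bloom per month; seasonal totals sum the
monthly values within a user-defined partition of the year (default UK
meteorological seasons, with winter wrapping December-February).
"""

from __future__ import annotations

import calendar
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["monthly_bloom_area", "seasonal_totals", "DEFAULT_SEASONS"]

DEFAULT_SEASONS: dict[str, tuple[int, ...]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}

REQUIRED_COLUMNS = ["crop", "area_ha", "bloom_start_month", "bloom_end_month"]


class PhenologyError(ValueError):
    """A crop row or season definition is invalid."""


def monthly_bloom_area(crops: pd.DataFrame) -> pd.Series:
    """Area (ha) of crop in bloom for each month 1-12.

    Each crop contributes area / n_bloom_months to every month in its
    window, so its contributions over the year sum exactly to its planted
    area.  An empty table yields an all-zero mapping.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in crops.columns]
    if missing:
        raise PhenologyError(f"crop table missing columns: {missing}")
    months = pd.Series(0.0, index=pd.RangeIndex(1, 13, name="month"), name="area_ha")
    for i, row in crops.iterrows():
        start, end = int(row.bloom_start_month), int(row.bloom_end_month)
        if not (1 <= start <= end <= 12):
            raise PhenologyError(
                f"row {i} ({row.crop}): bloom months must satisfy 1 <= start <= end <= 12"
            )
        if row.area_ha < 0:
            raise PhenologyError(f"row {i} ({row.crop}): area cannot be negative")
        n_months = end - start + 1
        months.loc[start:end] += float(row.area_ha) / n_months
    return months


def seasonal_totals(
    monthly: pd.Series, seasons: Mapping[str, Sequence[int]] | None = None
) -> pd.Series:
    """Sum monthly bloom areas within each season of a partition of months."""
    if seasons is None:
        seasons = DEFAULT_SEASONS
    claimed = [m for ms in seasons.values() for m in ms]
    if sorted(claimed) != list(range(1, 13)):
        raise PhenologyError(
            "season definition must partition months 1-12 exactly once each"
        )
    out = pd.Series(
        {name: float(monthly.loc[list(ms)].sum()) for name, ms in seasons.items()},
        name="area_ha",
    )
    out.index.name = "season"
    return out


def month_name(month: int) -> str:
    return calendar.month_name[month]
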