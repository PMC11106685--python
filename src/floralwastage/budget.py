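"""Field-scale supply / demand accounting for floral resources.

Per study day the budget chains together:

* flower density (flowers m^-2) = mean racemes per m^2 quadrat x mean open
  flowers per raceme;
* insect density (insects m^-2) = mean insects per transect / transect
  area (default 50 m x 1 m = 50 m^2);
* nectar supply per m^2 per h = flower density x per-flower secretion rate
  of bagged (inaccessible) flowers — the potential maximum, since short
  sampling intervals leave no time for reabsorption;
* per-insect supply = supply per m^2 / insect density;
* uncollected sugar per m^2 per h = flower density x accessible-flower
  accumulation rate (what insects left behind);
* field-scale rates in kg ha^-1 h^-1 and bumblebee colony equivalents
  (CE): sugar mass as a fraction of the 1186 g lifetime sugar intake of a
  Bombus terrestris colony.

Pooling across study days is the unweighted mean of per-day metrics; note
the mean of per-day per-insect ratios generally differs from the ratio of
grand means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DayBudget",
    "flower_density",
    "insect_density",
    "colony_equivalents",
    "day_budget",
    "pooled_budget",
    "community_composition",
    "packaged_community_table",
    "TRANSECT_AREA_M2",
    "COLONY_LIFETIME_SUGAR_G",
]

TRANSECT_AREA_M2 = 50.0  # 50 m walked, 1 m to one side
COLONY_LIFETIME_SUGAR_G = 1186.0  # lifetime sugar intake of one B. terrestris colony

UG_PER_M2_TO_KG_PER_HA = 1e-5  # ug m^-2 -> kg ha^-1: 1e-9 kg x 1e4 m^2/ha


class BudgetError(ValueError):
    """A budget input is missing or unusable."""


def flower_density(
    raceme_counts_per_m2: Sequence[float], flowers_per_raceme: Sequence[float]
) -> float:
    """Open flowers per m^2: mean racemes m^-2 x mean flowers per raceme."""
    rac = list(raceme_counts_per_m2)
    flw = list(flowers_per_raceme)
    if not rac or not flw:
        raise BudgetError("need >= 1 quadrat raceme count and >= 1 raceme flower count")
    return float(np.mean(rac) * np.mean(flw))


def insect_density(
    transect_counts: Sequence[float], transect_area_m2: float = TRANSECT_AREA_M2
) -> float:
    """Flower-visiting insects per m^2 from per-transect counts."""
    if transect_area_m2 <= 0:
        raise BudgetError("transect area must be strictly positive")
    counts = list(transect_counts)
    if not counts:
        raise BudgetError("need >= 1 transect count")
    return float(np.mean(counts) / transect_area_m2)


def colony_equivalents(
    sugar_kg_per_ha_h: float, colony_intake_g: float = COLONY_LIFETIME_SUGAR_G
) -> float:
    """Sugar flux expressed as bumblebee colony equivalents (CE ha^-1 h^-1)."""
    if colony_intake_g <= 0:
        raise BudgetError("colony lifetime sugar intake must be strictly positive")
    return sugar_kg_per_ha_h * 1000.0 / colony_intake_g


@dataclass(frozen=True)
class DayBudget:
    """All per-day supply/wastage metrics; per-insect fields are None when
    no insects were observed (division undefined, flagged not imputed)."""

    day: str
    flowers_per_m2: float
    insects_per_m2: float
    secretion_uL_flower_h: float  # inaccessible flowers
    secretion_ug_sugar_flower_h: float  # inaccessible flowers
    uncollected_ug_sugar_flower_h: float  # accessible flowers
    supply_uL_per_m2_h: float = field(init=False)
    supply_ug_sugar_per_m2_h: float = field(init=False)
    uncollected_ug_sugar_per_m2_h: float = field(init=False)
    supply_kg_sugar_per_ha_h: float = field(init=False)
    uncollected_kg_sugar_per_ha_h: float = field(init=False)
    supply_uL_per_insect_h: float | None = field(init=False)
    supply_g_sugar_per_insect_h: float | None = field(init=False)
    supply_colony_equiv_per_ha_h: float = field(init=False)
    uncollected_colony_equiv_per_ha_h: float = field(init=False)
    colony_intake_g: float = COLONY_LIFETIME_SUGAR_G

    def __post_init__(self):
        for name in (
            "flowers_per_m2", "insects_per_m2", "secretion_uL_flower_h",
            "secretion_ug_sugar_flower_h", "uncollected_ug_sugar_flower_h",
        ):
            if getattr(self, name) < 0:
                raise BudgetError(f"{name} cannot be negative")
        f = self.flowers_per_m2
        object.__setattr__(self, "supply_uL_per_m2_h", f * self.secretion_uL_flower_h)
        object.__setattr__(
            self, "supply_ug_sugar_per_m2_h", f * self.secretion_ug_sugar_flower_h
        )
        object.__setattr__(
            self,
            "uncollected_ug_sugar_per_m2_h",
            f * self.uncollected_ug_sugar_flower_h,
        )
        object.__setattr__(
            self,
            "supply_kg_sugar_per_ha_h",
            self.supply_ug_sugar_per_m2_h * UG_PER_M2_TO_KG_PER_HA,
        )
        object.__setattr__(
            self,
            "uncollected_kg_sugar_per_ha_h",
            self.uncollected_ug_sugar_per_m2_h * UG_PER_M2_TO_KG_PER_HA,
        )
        if self.insects_per_m2 > 0:
            object.__setattr__(
                self,
                "supply_uL_per_insect_h",
                self.supply_uL_per_m2_h / self.insects_per_m2,
            )
            object.__setattr__(
                self,
                "supply_g_sugar_per_insect_h",
                self.supply_ug_sugar_per_m2_h / self.insects_per_m2 * 1e-6,
            )
        else:
            object.__setattr__(self, "supply_uL_per_insect_h", None)
            object.__setattr__(self, "supply_g_sugar_per_insect_h", None)
        object.__setattr__(
            self,
            "supply_colony_equiv_per_ha_h",
            colony_equivalents(self.supply_kg_sugar_per_ha_h, self.colony_intake_g),
        )
        object.__setattr__(
            self,
            "uncollected_colony_equiv_per_ha_h",
            colony_equivalents(
                self.uncollected_kg_sugar_per_ha_h, self.colony_intake_g
            ),
        )


def day_budget(
    day: str,
    raceme_counts_per_m2: Sequence[float],
    flowers_per_raceme: Sequence[float],
    transect_counts: Sequence[float],
    secretion_uL_flower_h: float,
    secretion_ug_sugar_flower_h: float,
    uncollected_ug_sugar_flower_h: float,
    transect_area_m2: float = TRANSECT_AREA_M2,
    colony_intake_g: float = COLONY_LIFETIME_SUGAR_G,
) -> DayBudget:
    """Assemble one study day's budget from its raw survey inputs."""
    return DayBudget(
        day=day,
        flowers_per_m2=flower_density(raceme_counts_per_m2, flowers_per_raceme),
        insects_per_m2=insect_density(transect_counts, transect_area_m2),
        secretion_uL_flower_h=secretion_uL_flower_h,
        secretion_ug_sugar_flower_h=secretion_ug_sugar_flower_h,
        uncollected_ug_sugar_flower_h=uncollected_ug_sugar_flower_h,
        colony_intake_g=colony_intake_g,
    )


_POOLED_FIELDS = [
    "flowers_per_m2",
    "insects_per_m2",
    "secretion_uL_flower_h",
    "secretion_ug_sugar_flower_h",
    "uncollected_ug_sugar_flower_h",
    "supply_uL_per_m2_h",
    "supply_ug_sugar_per_m2_h",
    "uncollected_ug_sugar_per_m2_h",
    "supply_kg_sugar_per_ha_h",
    "uncollected_kg_sugar_per_ha_h",
    "supply_colony_equiv_per_ha_h",
    "uncollected_colony_equiv_per_ha_h",
    "supply_uL_per_insect_h",
    "supply_g_sugar_per_insect_h",
]


def pooled_budget(day_budgets: Sequence[DayBudget]) -> dict:
    """Unweighted mean of each per-day metric over study days.

    Per-insect metrics average only over days where they are defined; the
    number of undefined (zero-insect) days is reported alongside.
    """
    if not day_budgets:
        raise BudgetError("need >= 1 day budget to pool")
    out: dict = {"n_days": len(day_budgets)}
    for name in _POOLED_FIELDS:
        vals = [getattr(b, name) for b in day_budgets]
        defined = [v for v in vals if v is not None]
        out[name] = float(np.mean(defined)) if defined else None
        if name == "supply_uL_per_insect_h":
            out["n_days_undefined_per_insect"] = len(vals) - len(defined)
    return out


# ---------------------------------------------------------------------------
# flower-visiting insect community


def packaged_community_table() -> pd.DataFrame:
    """The observed transect community of an OSR bloom survey.

    Species-level totals over 581 50-m^2 transects, grouped as honeybee,
    bumblebee, non-apid bee and non-bee.
    """
    with resources.files("floralwastage.data").joinpath(
        "osr_transect_community.csv"
    ).open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def community_composition(table: pd.DataFrame) -> dict:
    """Group totals and percentage shares of a (taxon, group, count) table."""
    if not {"group", "count"} <= set(table.columns):
        raise BudgetError("community table needs 'group' and 'count' columns")
    totals = table.groupby("group", observed=True)["count"].sum().to_dict()
    total = int(table["count"].sum())
    if total == 0:
        raise BudgetError("community table has zero insects")
    get = lambda g: int(totals.get(g, 0))  # noqa: E731
    bees_social = get("honeybee") + get("bumblebee")
    return {
        "total": total,
        "honeybees": get("honeybee"),
        "bumblebees": get("bumblebee"),
        "non_apid_bees": get("non_apid_bee"),
        "non_bees": get("non_bee"),
        "honeybee_pct": 100.0 * get("honeybee") / total,
        "bumblebee_pct": 100.0 * get("bumblebee") / total,
        "honeybee_plus_bumblebee_pct": 100.0 * bees_social / total,
    }
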