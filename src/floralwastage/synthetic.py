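"""Synthetic field-study generator with the design of the wastage survey.

Emulates a two-year paired-flower exclusion study on a mass-flowering
crop: four fields (sites) per year, one field surveyed per study day, and
on each day

* 10 flower pairs (5 edge, 5 interior), each pair one accessible and one
  gauze-bagged (inaccessible) flower on the same plant, drained and
  re-sampled up to three times (periods T1-T3) roughly 142 min apart;
* anthers collected at the beginning and end of anthesis for
  haemocytometer pollen counts;
* ten 50 m insect transects per period (5 edge, 5 interior);
* ~31 one-m^2 quadrats (raceme counts) and ~24 raceme flower counts;
* hourly temperature / relative humidity.

The generator's defaults are the study's own summary statistics: mean
inaccessible nectar secretion 0.10 +/- 0.08 uL flower^-1 h^-1, Brix
42 +/- 15 %, accessible flowers accumulating 69% of inaccessible
(rho_nectar), end-of-anthesis pollen 19% of beginning (rho_pollen),
interior insect mean 0.71 per transect with an edge multiplier of
1.31/0.71, raceme density 46 +/- 25 m^-2 and 7 +/- 5 flowers per raceme.
Nectar rates are lognormal (the reported SDs are of the same order as the
means, implying strong right skew), moment-matched to the stated
mean/SD.  Nested multiplicative random effects (year, site-within-year,
day-within-site, plant) are mean-one lognormal with configurable SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SimulationParams", "CropSpec", "generate_study", "generate_crop_table"]

PERIODS = ("T1", "T2", "T3")
LOCATIONS = ("edge", "interior")
TREATMENTS = ("accessible", "inaccessible")
STAGES = ("begin", "end")

# taxon sampling weights for transect counts, shaped like the observed
# community (dominated by honeybees, then bumblebees)
_TAXON_WEIGHTS = {
    "Apis mellifera": 0.71,
    "Bombus terrestris agg.": 0.15,
    "Bombus lapidarius": 0.04,
    "Andrena spp.": 0.035,
    "Diptera": 0.06,
    "Lepidoptera": 0.005,
}


class SimulationError(ValueError):
    """Simulation parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class CropSpec:
    """One mass-flowering crop: planted area and inclusive bloom window."""

    crop: str
    area_ha: float
    bloom_start_month: int
    bloom_end_month: int


@dataclass(frozen=True)
class SimulationParams:
    """Tunable parameters of the synthetic study; defaults mirror the survey."""

    years: tuple[int, ...] = (2021, 2023)
    sites_per_year: int = 4
    days_per_site: tuple[int, ...] = (3, 2)  # per year, totals 20 study days
    pairs_per_day: int = 10  # 5 edge + 5 interior
    periods_per_day: int = 3

    # nectar
    rho_nectar: float = 0.69  # accessible / inaccessible accumulation ratio
    secretion_mean_uL_h: float = 0.10  # inaccessible flowers
    secretion_sd_uL_h: float = 0.08
    brix_mean: float = 42.0
    brix_sd: float = 15.0
    interval_mean_min: float = 142.0
    interval_sd_min: float = 26.0

    # pollen (summed 4-corner haemocytometer counts)
    pollen_begin_mean: float = 167.0
    rho_pollen: float = 0.19  # end / begin count ratio
    pollen_nb_size: float = 2.0
    anthers_per_day_per_stage: int = 6

    # insects per 50 m transect
    insect_interior_mean: float = 0.71
    insect_edge_multiplier: float = 1.31 / 0.71
    insect_nb_size: float = 0.8
    transects_per_period_per_location: int = 5

    # flower density surveys
    quadrats_per_day: int = 31
    raceme_mean_per_m2: float = 46.0
    raceme_sd_per_m2: float = 25.0
    raceme_counts_per_day: int = 24
    flowers_per_raceme_mean: float = 7.0
    flowers_per_raceme_sd: float = 5.0

    # nested mean-one lognormal random effects (SD on the log scale)
    year_effect_sd: float = 0.10
    site_effect_sd: float = 0.15
    day_effect_sd: float = 0.15
    plant_effect_sd: float = 0.20

    # weather
    temp_mean_c: float = 15.0
    temp_sd_c: float = 3.0
    rh_mean_pct: float = 70.0
    rh_sd_pct: float = 10.0
    hours_per_day: int = 9

    crops: tuple[CropSpec, ...] = (
        CropSpec("oilseed rape", 364_000, 4, 6),
        CropSpec("field bean", 170_000, 6, 7),
        CropSpec("field pea", 50_000, 6, 7),
        CropSpec("flax", 10_000, 6, 8),
        CropSpec("orchard fruit", 25_000, 4, 5),
        CropSpec("soft fruit", 10_000, 5, 8),
    )

    def validate(self) -> None:
        if len(self.days_per_site) != len(self.years):
            raise SimulationError("days_per_site must give one entry per year")
        positive = (
            "sites_per_year pairs_per_day periods_per_day rho_nectar "
            "secretion_mean_uL_h secretion_sd_uL_h brix_mean brix_sd "
            "interval_mean_min pollen_begin_mean rho_pollen pollen_nb_size "
            "anthers_per_day_per_stage insect_interior_mean "
            "insect_edge_multiplier insect_nb_size "
            "transects_per_period_per_location quadrats_per_day "
            "raceme_mean_per_m2 raceme_sd_per_m2 raceme_counts_per_day "
            "flowers_per_raceme_mean flowers_per_raceme_sd hours_per_day"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be strictly positive")
        if self.periods_per_day > len(PERIODS):
            raise SimulationError(f"at most {len(PERIODS)} periods per day")
        if self.pairs_per_day % 2:
            raise SimulationError("pairs_per_day must split evenly between edge/interior")
        for sd in (self.year_effect_sd, self.site_effect_sd, self.day_effect_sd,
                   self.plant_effect_sd):
            if sd < 0:
                raise SimulationError("random-effect SDs must be non-negative")


def _mean_one_lognormal(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """Multiplicative effect with E[effect] = 1 and log-scale SD ``sd``."""
    if sd == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sd**2, sigma=sd, size=size)


def _lognormal_from_moments(rng: np.random.Generator, mean, sd, size=None) -> np.ndarray:
    """Lognormal draws moment-matched to an arithmetic mean and SD."""
    mean = np.asarray(mean, dtype=float)
    cv2 = (np.asarray(sd, dtype=float) / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out <= low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= low) | (out > high)
    return out


def _nb_counts(rng: np.random.Generator, mean, size_param: float, n: int) -> np.ndarray:
    """Negative binomial counts with arithmetic mean ``mean`` and size k."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (n,))
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _study_days(params: SimulationParams) -> pd.DataFrame:
    rows = []
    day_id = 0
    for yi, year in enumerate(params.years):
        for s in range(1, params.sites_per_year + 1):
            for _ in range(params.days_per_site[yi]):
                day_id += 1
                rows.append({"year": year, "site": f"S{s}", "day": f"D{day_id:03d}"})
    return pd.DataFrame(rows)


def generate_study(params: SimulationParams | None = None, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Draw one complete synthetic study.

    Returns a dict of tidy tables: ``nectar`` (paired flower samples),
    ``pollen`` (corner-square counts per anther), ``insects`` (transect
    counts by taxon), ``flowers`` (quadrat raceme counts and
    flowers-per-raceme counts, distinguished by ``kind``) and ``weather``
    (hourly T / RH per study day).  Identical ``params`` and ``seed``
    give identical tables.
    """
    if params is None:
        params = SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)

    days = _study_days(params)
    n_days = len(days)

    # nested mean-one multiplicative effects shared across response types
    year_eff = {y: _mean_one_lognormal(rng, params.year_effect_sd) for y in params.years}
    site_eff = {
        (y, f"S{s}"): _mean_one_lognormal(rng, params.site_effect_sd)
        for y in params.years
        for s in range(1, params.sites_per_year + 1)
    }
    day_eff = {d: _mean_one_lognormal(rng, params.day_effect_sd) for d in days["day"]}

    cv = params.secretion_sd_uL_h / params.secretion_mean_uL_h
    periods = PERIODS[: params.periods_per_day]
    half_pairs = params.pairs_per_day // 2

    nectar_rows: list[dict] = []
    for _, drow in days.iterrows():
        base = (
            params.secretion_mean_uL_h
            * year_eff[drow.year]
            * site_eff[(drow.year, drow.site)]
            * day_eff[drow.day]
        )
        for loc_i, location in enumerate(LOCATIONS):
            for p in range(half_pairs):
                pair = f"{drow.day}-{location}-P{p + 1}"
                plant = _mean_one_lognormal(rng, params.plant_effect_sd)
                pair_mean = base * plant
                for period in periods:
                    interval = float(
                        np.clip(
                            rng.normal(params.interval_mean_min, params.interval_sd_min),
                            60.0,
                            210.0,
                        )
                    )
                    for treatment in TREATMENTS:
                        mean_rate = pair_mean * (
                            params.rho_nectar if treatment == "accessible" else 1.0
                        )
                        rate = float(
                            _lognormal_from_moments(rng, mean_rate, cv * mean_rate)
                        )
                        brix = float(
                            _truncated_normal(
                                rng, params.brix_mean, params.brix_sd, 0.0, 70.0,
                                np.empty(1).shape,
                            )[0]
                        )
                        nectar_rows.append(
                            {
                                "year": drow.year,
                                "site": drow.site,
                                "day": drow.day,
                                "period": period,
                                "location": location,
                                "pair": pair,
                                "treatment": treatment,
                                "interval_min": round(interval, 1),
                                "volume_uL": rate * interval / 60.0,
                                "brix_pct": brix,
                            }
                        )
    nectar = pd.DataFrame(nectar_rows)

    pollen_rows: list[dict] = []
    for _, drow in days.iterrows():
        base = (
            params.pollen_begin_mean
            * year_eff[drow.year]
            * site_eff[(drow.year, drow.site)]
            * day_eff[drow.day]
        )
        for stage in STAGES:
            mean = base * (params.rho_pollen if stage == "end" else 1.0)
            n = params.anthers_per_day_per_stage
            counts = _nb_counts(rng, mean, params.pollen_nb_size, n)
            for i, total in enumerate(counts):
                corners = rng.multinomial(int(total), [0.25] * 4)
                pollen_rows.append(
                    {
                        "year": drow.year,
                        "site": drow.site,
                        "day": drow.day,
                        "location": LOCATIONS[i % 2],
                        "stage": stage,
                        "corner1": int(corners[0]),
                        "corner2": int(corners[1]),
                        "corner3": int(corners[2]),
                        "corner4": int(corners[3]),
                    }
                )
    pollen = pd.DataFrame(pollen_rows)

    taxa = list(_TAXON_WEIGHTS)
    taxon_p = np.array(list(_TAXON_WEIGHTS.values()))
    taxon_p = taxon_p / taxon_p.sum()
    insect_rows: list[dict] = []
    for _, drow in days.iterrows():
        deff = day_eff[drow.day] * year_eff[drow.year] * site_eff[(drow.year, drow.site)]
        for period in periods:
            t_id = 0
            for location in LOCATIONS:
                mult = params.insect_edge_multiplier if location == "edge" else 1.0
                mean = params.insect_interior_mean * mult * deff
                counts = _nb_counts(
                    rng, mean, params.insect_nb_size,
                    params.transects_per_period_per_location,
                )
                for c in counts:
                    t_id += 1
                    transect = f"{drow.day}-{period}-T{t_id}"
                    if c == 0:
                        insect_rows.append(
                            {
                                "year": drow.year, "site": drow.site, "day": drow.day,
                                "period": period, "location": location,
                                "transect": transect, "taxon": "none", "count": 0,
                            }
                        )
                        continue
                    split = rng.multinomial(int(c), taxon_p)
                    for taxon, k in zip(taxa, split):
                        if k > 0:
                            insect_rows.append(
                                {
                                    "year": drow.year, "site": drow.site, "day": drow.day,
                                    "period": period, "location": location,
                                    "transect": transect, "taxon": taxon, "count": int(k),
                                }
                            )
    insects = pd.DataFrame(insect_rows)

    flower_rows: list[dict] = []
    for _, drow in days.iterrows():
        deff = day_eff[drow.day] * year_eff[drow.year] * site_eff[(drow.year, drow.site)]
        rac = _nb_counts(
            rng, params.raceme_mean_per_m2 * deff,
            _nb_size_from_moments(params.raceme_mean_per_m2, params.raceme_sd_per_m2),
            params.quadrats_per_day,
        )
        for i, c in enumerate(rac):
            flower_rows.append(
                {
                    "year": drow.year, "site": drow.site, "day": drow.day,
                    "location": LOCATIONS[i % 2], "kind": "quadrat_racemes",
                    "unit": f"{drow.day}-Q{i + 1}", "count": int(c),
                }
            )
        fl = _nb_counts(
            rng, params.flowers_per_raceme_mean,
            _nb_size_from_moments(params.flowers_per_raceme_mean, params.flowers_per_raceme_sd),
            params.raceme_counts_per_day,
        )
        for i, c in enumerate(fl):
            flower_rows.append(
                {
                    "year": drow.year, "site": drow.site, "day": drow.day,
                    "location": LOCATIONS[i % 2], "kind": "raceme_flowers",
                    "unit": f"{drow.day}-R{i + 1}", "count": int(c),
                }
            )
    flowers = pd.DataFrame(flower_rows)

    weather_rows: list[dict] = []
    for _, drow in days.iterrows():
        temps = rng.normal(params.temp_mean_c, params.temp_sd_c, params.hours_per_day)
        rhs = np.clip(
            rng.normal(params.rh_mean_pct, params.rh_sd_pct, params.hours_per_day), 5, 100
        )
        for h in range(params.hours_per_day):
            weather_rows.append(
                {
                    "year": drow.year, "site": drow.site, "day": drow.day,
                    "hour": 8 + h,
                    "temperature_c": round(float(temps[h]), 2),
                    "relative_humidity_pct": round(float(rhs[h]), 1),
                }
            )
    weather = pd.DataFrame(weather_rows)

    return {
        "nectar": nectar,
        "pollen": pollen,
        "insects": insects,
        "flowers": flowers,
        "weather": weather,
    }


def _nb_size_from_moments(mean: float, sd: float) -> float:
    """NB size parameter k with var = mean + mean^2/k matching (mean, sd)."""
    excess = sd**2 - mean
    if excess <= 0:  # at or below Poisson dispersion; use a large k
        return 1e6
    return mean**2 / excess


def generate_crop_table(
    params: SimulationParams | None = None, crops: Sequence[CropSpec] | None = None
) -> pd.DataFrame:
    """Crop bloom table (crop, area_ha, bloom_start_month, bloom_end_month).

    Areas and bloom windows are user-configurable; the defaults are
    illustrative UK mass-flowering crops for exercising the phenology
    module, not a published dataset.
    """
    if crops is None:
        crops = (params or SimulationParams()).crops
    rows = []
    for c in crops:
        if c.area_ha <= 0:
            raise SimulationError(f"{c.crop}: area must be positive")
        if not (1 <= c.bloom_start_month <= c.bloom_end_month <= 12):
            raise SimulationError(
                f"{c.crop}: bloom months must satisfy 1 <= start <= end <= 12"
            )
        rows.append(
            {
                "crop": c.crop,
                "area_ha": float(c.area_ha),
                "bloom_start_month": int(c.bloom_start_month),
                "bloom_end_month": int(c.bloom_end_month),
            }
        )
    return pd.DataFrame(
        rows, columns=["crop", "area_ha", "bloom_start_month", "bloom_end_month"]
    )


def with_params(params: SimulationParams, **changes) -> SimulationParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **changes)
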