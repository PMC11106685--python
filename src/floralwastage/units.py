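"""Measurement-to-quantity conversions for nectar, pollen and weather data.

Field measurements arrive in instrument units: nectar as the length of the
liquid column in a calibrated microcapillary tube, sugar concentration as
refractometer % Brix, pollen as counts in haemocytometer corner squares,
and weather as hourly temperature / relative humidity.  This module turns
each of those into the physical quantity the downstream analysis needs:

* nectar volume (uL) from capillary column length,
* sugar mass per unit nectar volume (ug/uL) from % Brix via a packaged
  sucrose solution density table with linear interpolation,
* per-hour accumulation rates from quantities measured over an interval,
* pollen-grain totals and per-anther estimates from corner-square counts,
* vapour pressure deficit (kPa) from temperature and relative humidity
  using the Tetens saturation formula.

Brix is treated throughout as % mass/mass sucrose equivalents with no
temperature correction of refractometer readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SugarDensityTable",
    "CapillarySpec",
    "HaemocytometerSpec",
    "capillary_volume",
    "brix_to_sugar_per_uL",
    "nectar_sugar_mass",
    "accumulation_rate",
    "pollen_suspension_count",
    "pollen_per_anther",
    "vpd",
    "daily_mean_vpd",
]


class MeasurementError(ValueError):
    """An input measurement is physically impossible or out of range."""


@dataclass(frozen=True)
class SugarDensityTable:
    """Density of aqueous sucrose solutions versus % mass/mass concentration.

    Wraps rows of (Brix %, density g/mL) spanning at least 0-70% in
    increments of 2% or finer, as published in standard handbook tables of
    concentrative properties of sucrose solutions at 20 degC.  Conversions
    between nodes use linear interpolation; the interpolation error is
    negligible at these increments.
    """

    brix_pct: np.ndarray
    density_g_per_ml: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.brix_pct, dtype=float)
        d = np.asarray(self.density_g_per_ml, dtype=float)
        if b.ndim != 1 or b.shape != d.shape or b.size < 2:
            raise ValueError("table needs matching 1-D concentration/density arrays")
        if not np.all(np.diff(b) > 0):
            raise ValueError("Brix concentrations must be strictly increasing")
        if not np.all(np.diff(d) > 0):
            raise ValueError("densities must be strictly increasing with concentration")
        if b[0] == 0 and not (0.995 <= d[0] <= 1.000):
            raise ValueError("density at 0% Brix must lie in 0.995-1.000 g/mL")
        object.__setattr__(self, "brix_pct", b)
        object.__setattr__(self, "density_g_per_ml", d)

    @classmethod
    def packaged(cls) -> "SugarDensityTable":
        """The sucrose density table shipped with the package (0-70%, 2% steps)."""
        with resources.files("floralwastage.data").joinpath("sucrose_density.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls(df["brix_pct"].to_numpy(), df["density_g_per_ml"].to_numpy())

    def density(self, brix: float) -> float:
        """Linearly interpolated solution density (g/mL) at ``brix`` % m/m."""
        if not (self.brix_pct[0] <= brix <= self.brix_pct[-1]):
            raise MeasurementError(
                f"Brix {brix}% outside table range "
                f"[{self.brix_pct[0]}, {self.brix_pct[-1]}]; no extrapolation"
            )
        return float(np.interp(brix, self.brix_pct, self.density_g_per_ml))


@dataclass(frozen=True)
class CapillarySpec:
    """Nominal volume (uL) and length (mm) of the nectar sampling capillary."""

    volume_uL: float = 1.0
    length_mm: float = 32.0

    def __post_init__(self) -> None:
        if self.volume_uL <= 0 or self.length_mm <= 0:
            raise ValueError("capillary volume and length must be strictly positive")


@dataclass(frozen=True)
class HaemocytometerSpec:
    """Counting-chamber geometry and suspension volumes for pollen counts.

    Defaults are a Neubauer-type chamber (1 mm^2 corner square, 0.1 mm
    depth) with the protocol volumes: one anther suspended in 15 uL, of
    which a 10 uL aliquot is loaded on the chamber.
    """

    square_area_mm2: float = 1.0
    depth_mm: float = 0.1
    suspension_uL: float = 15.0
    aliquot_uL: float = 10.0

    def __post_init__(self) -> None:
        for name in ("square_area_mm2", "depth_mm", "suspension_uL", "aliquot_uL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def square_volume_uL(self) -> float:
        # 1 mm^3 == 1 uL
        return self.square_area_mm2 * self.depth_mm


def capillary_volume(column_length_mm: float, spec: CapillarySpec = CapillarySpec()) -> float:
    """Nectar volume (uL) from the liquid column length in the capillary.

    The tube bore is uniform, so volume is the fraction of tube length
    occupied times the nominal tube volume.
    """
    if column_length_mm < 0:
        raise MeasurementError("column length cannot be negative")
    if column_length_mm > spec.length_mm:
        raise MeasurementError(
            f"column length {column_length_mm} mm exceeds tube length {spec.length_mm} mm"
        )
    return (column_length_mm / spec.length_mm) * spec.volume_uL


def brix_to_sugar_per_uL(brix: float, table: SugarDensityTable | None = None) -> float:
    """Sugar mass per unit nectar volume (ug sugar / uL nectar) at ``brix`` % m/m.

    A solution of b % mass/mass at density rho g/mL carries
    (b/100) * rho grams of sugar per mL, i.e. (b/100) * rho * 1000 ug/uL.
    """
    if table is None:
        table = SugarDensityTable.packaged()
    rho = table.density(brix)  # raises outside range
    return (brix / 100.0) * rho * 1000.0


def nectar_sugar_mass(
    volume_uL: float, brix: float, table: SugarDensityTable | None = None
) -> float:
    """Sugar mass (ug) in a nectar sample of ``volume_uL`` at ``brix`` % m/m."""
    if volume_uL < 0:
        raise MeasurementError("nectar volume cannot be negative")
    if volume_uL == 0:
        return 0.0
    return volume_uL * brix_to_sugar_per_uL(brix, table)


def accumulation_rate(quantity: float, interval_min: float) -> float:
    """Per-hour accumulation rate from a quantity accrued over ``interval_min``.

    Works for any linear quantity (uL nectar, ug sugar).
    """
    if interval_min <= 0:
        raise MeasurementError("interval must be strictly positive")
    return quantity * 60.0 / interval_min


def pollen_suspension_count(corner_counts: Sequence[int]) -> int:
    """Total pollen grains over the four haemocytometer corner squares.

    This sum is the response variable of the pollen wastage analysis.
    """
    counts = list(corner_counts)
    if len(counts) != 4:
        raise MeasurementError(f"expected exactly 4 corner-square counts, got {len(counts)}")
    for c in counts:
        if c < 0 or c != int(c):
            raise MeasurementError("corner counts must be non-negative integers")
    return int(sum(counts))


def pollen_per_anther(
    corner_counts: Sequence[int], spec: HaemocytometerSpec = HaemocytometerSpec()
) -> float:
    """Estimated pollen grains in the whole anther from corner-square counts.

    The mean count per corner square divided by the square's volume gives
    grain concentration in the aliquot; assuming the aliquot is well mixed,
    that concentration holds for the whole suspension, so multiplying by
    the suspension volume recovers the total grains released by the anther.
    The aliquot volume itself cancels and does not enter.
    """
    total = pollen_suspension_count(corner_counts)
    mean_per_square = total / 4.0
    return mean_per_square / spec.square_volume_uL * spec.suspension_uL


def vpd(temperature_c: float, relative_humidity_pct: float) -> float:
    """Vapour pressure deficit (kPa) from air temperature and RH.

    Saturation vapour pressure follows the Tetens formula
    ``es = 0.6108 * exp(17.27 T / (T + 237.3))`` kPa; the deficit is
    ``es * (1 - RH/100)``.  VPD controls the evaporative concentration of
    exposed nectar and is reported as study-day context.
    """
    rh = relative_humidity_pct
    if not (0.0 <= rh <= 100.0):
        raise MeasurementError(f"relative humidity {rh}% outside [0, 100]")
    es = 0.6108 * np.exp(17.27 * temperature_c / (temperature_c + 237.3))
    return float(es * (1.0 - rh / 100.0))


def daily_mean_vpd(
    temperatures_c: Iterable[float], relative_humidities_pct: Iterable[float]
) -> float:
    """Arithmetic mean VPD (kPa) over paired hourly T / RH readings."""
    temps = list(temperatures_c)
    rhs = list(relative_humidities_pct)
    if len(temps) != len(rhs) or not temps:
        raise MeasurementError("need equal-length, non-empty hourly T and RH series")
    return float(np.mean([vpd(t, r) for t, r in zip(temps, rhs)]))
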