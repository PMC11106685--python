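"""Table schemas, run configuration and the end-to-end pipeline.

All pipeline inputs are UTF-8 CSV files with a header row and "." decimal
separator, one record per row.  Year and site travel as explicit columns
because the random-effect structure (site nested within year) needs both.
``read_table`` validates against a declared schema — column presence,
numeric parsability, categorical levels, range constraints — and rejects
bad rows with row-numbered messages.

``run_pipeline`` chains the whole analysis: simulate or load the input
tables, convert measurements to rates, fit the nectar mixed model and the
pollen/insect count models, bootstrap the wastage ratios over study days,
assemble per-day and pooled resource budgets, and tabulate crop bloom
phenology.  Identical configuration and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import budget as bdg
from . import phenology as phen
from . import stats as st
from . import synthetic as syn
from .units import SugarDensityTable, daily_mean_vpd

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "RowValidationError",
    "ConfigError",
    "read_table",
    "write_table",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("floralwastage")


class SchemaError(ValueError):
    """The file's header does not match the declared schema."""


class RowValidationError(ValueError):
    """One or more rows failed validation; message lists row numbers."""


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # "int" | "float" | "str"
    levels: tuple[str, ...] | None = None
    minimum: float | None = None
    maximum: float | None = None
    nullable: bool = False


SCHEMAS: dict[str, tuple[Column, ...]] = {
    "nectar": (
        Column("year", "int"),
        Column("site", "str"),
        Column("day", "str"),
        Column("period", "str", levels=("T1", "T2", "T3")),
        Column("location", "str", levels=("edge", "interior")),
        Column("pair", "str"),
        Column("treatment", "str", levels=("accessible", "inaccessible")),
        Column("interval_min", "float", minimum=np.nextafter(0, 1)),
        Column("volume_uL", "float", minimum=0.0),
        Column("brix_pct", "float", minimum=0.0, maximum=100.0, nullable=True),
    ),
    "pollen": (
        Column("year", "int"),
        Column("site", "str"),
        Column("day", "str"),
        Column("location", "str", levels=("edge", "interior")),
        Column("stage", "str", levels=("begin", "end")),
        Column("corner1", "int", minimum=0),
        Column("corner2", "int", minimum=0),
        Column("corner3", "int", minimum=0),
        Column("corner4", "int", minimum=0),
    ),
    "insects": (
        Column("year", "int"),
        Column("site", "str"),
        Column("day", "str"),
        Column("period", "str", levels=("T1", "T2", "T3")),
        Column("location", "str", levels=("edge", "interior")),
        Column("transect", "str"),
        Column("taxon", "str"),
        Column("count", "int", minimum=0),
    ),
    "flowers": (
        Column("year", "int"),
        Column("site", "str"),
        Column("day", "str"),
        Column("location", "str", levels=("edge", "interior")),
        Column("kind", "str", levels=("quadrat_racemes", "raceme_flowers")),
        Column("unit", "str"),
        Column("count", "int", minimum=0),
    ),
    "weather": (
        Column("year", "int"),
        Column("site", "str"),
        Column("day", "str"),
        Column("hour", "int", minimum=0, maximum=23),
        Column("temperature_c", "float"),
        Column("relative_humidity_pct", "float", minimum=0.0, maximum=100.0),
    ),
    "crops": (
        Column("crop", "str"),
        Column("area_ha", "float", minimum=0.0),
        Column("bloom_start_month", "int", minimum=1, maximum=12),
        Column("bloom_end_month", "int", minimum=1, maximum=12),
    ),
}


def _coerce(value, col: Column, row_no: int, errors: list[str]):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if col.nullable:
            return np.nan
        errors.append(f"row {row_no}: missing value in '{col.name}'")
        return None
    if col.kind == "str":
        sval = str(value)
        if col.levels is not None and sval not in col.levels:
            errors.append(
                f"row {row_no}: '{col.name}' level {sval!r} not in declared "
                f"levels {list(col.levels)}"
            )
            return None
        return sval
    try:
        num = float(value)
    except (TypeError, ValueError):
        errors.append(f"row {row_no}: '{col.name}' value {value!r} is not numeric")
        return None
    if col.kind == "int":
        if num != int(num):
            errors.append(f"row {row_no}: '{col.name}' value {value!r} is not an integer")
            return None
        num = int(num)
    if col.minimum is not None and num < col.minimum:
        errors.append(f"row {row_no}: '{col.name}' value {num} below minimum {col.minimum}")
        return None
    if col.maximum is not None and num > col.maximum:
        errors.append(f"row {row_no}: '{col.name}' value {num} above maximum {col.maximum}")
        return None
    return num


def read_table(path: str | Path | io.TextIOBase, schema: str) -> pd.DataFrame:
    """Read and validate one pipeline CSV against a named schema.

    Raises ``SchemaError`` if columns are missing and ``RowValidationError``
    with row-numbered messages if any record fails validation.  An empty
    file with a valid header yields an empty, correctly-typed frame.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=object, keep_default_na=True)
    missing = [c.name for c in cols if c.name not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table missing columns: {missing}")
    errors: list[str] = []
    out = {}
    for col in cols:
        out[col.name] = [
            _coerce(v, col, i + 2, errors)  # +2: header line is row 1
            for i, v in enumerate(df[col.name])
        ]
    if errors:
        raise RowValidationError(
            f"{len(errors)} validation error(s) in {schema} table:\n  "
            + "\n  ".join(errors[:50])
        )
    typed = pd.DataFrame(out, columns=[c.name for c in cols])
    for col in cols:
        if col.kind == "int":
            typed[col.name] = typed[col.name].astype("int64")
        elif col.kind == "float":
            typed[col.name] = typed[col.name].astype(float)
        else:
            typed[col.name] = typed[col.name].astype(str)
    log.info("read %s table: %d records", schema, len(typed))
    return typed


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a pipeline table as CSV (UTF-8, '.' decimal, header row)."""
    if schema is not None:
        missing = [c.name for c in SCHEMAS[schema] if c.name not in df.columns]
        if missing:
            raise SchemaError(f"{schema} table missing columns: {missing}")
        df = df[[c.name for c in SCHEMAS[schema]]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything a pipeline run needs; either input paths or simulation.

    ``inputs`` maps schema names (nectar, pollen, insects, flowers,
    weather, crops) to CSV paths.  If ``simulate`` is true the tables come
    from the synthetic generator instead and ``sim_params`` applies.
    """

    simulate: bool = True
    inputs: dict[str, str] = field(default_factory=dict)
    sim_params: syn.SimulationParams = field(default_factory=syn.SimulationParams)
    seed: int = 0
    bootstrap: int = 1000
    alpha: float = 0.05
    transect_area_m2: float = bdg.TRANSECT_AREA_M2
    colony_intake_g: float = bdg.COLONY_LIFETIME_SUGAR_G
    seasons: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(phen.DEFAULT_SEASONS)
    )
    output_dir: str | None = None

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise ConfigError("either simulate=true or input paths must be given")
        if self.seed < 0 or self.seed != int(self.seed):
            raise ConfigError("seed must be a non-negative integer")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.bootstrap < 0:
            raise ConfigError("bootstrap replicate count cannot be negative")
        for name in ("transect_area_m2", "colony_intake_g"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not self.simulate:
            for schema, p in self.inputs.items():
                if schema not in SCHEMAS:
                    raise ConfigError(f"unknown input table {schema!r}")
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
        self.sim_params.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load configuration from YAML or JSON (both accepted)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        sim_kwargs = data.pop("sim_params", {})
        if "crops" in sim_kwargs:
            sim_kwargs["crops"] = tuple(syn.CropSpec(**c) for c in sim_kwargs["crops"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if sim_kwargs:
            cfg.sim_params = dataclasses.replace(cfg.sim_params, **sim_kwargs)
        return cfg


# ---------------------------------------------------------------------------
# pipeline


def _marginal_ratio(nectar_rates: pd.DataFrame) -> float:
    """Accessible/inaccessible ratio (x100) of equal-weight marginal means
    of aggregated cell means — the fast statistic used inside the bootstrap."""
    agg = st.aggregate_means(nectar_rates)
    marg = agg.groupby("treatment", observed=True)["mean_rate"].mean()
    return 100.0 * marg["accessible"] / marg["inaccessible"]


def _pollen_ratio(pollen: pd.DataFrame) -> float:
    marg = pollen.groupby("stage", observed=True)["count"].mean()
    return 100.0 * marg["end"] / marg["begin"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full wastage analysis and return a result bundle.

    The bundle maps result names to DataFrames / dicts: ``estimates``
    (wastage percentages with bootstrap CIs), ``nectar_fit`` /
    ``pollen_fit`` / ``insect_fit`` summaries, ``budget_days``,
    ``budget_pooled``, ``phenology_monthly``, ``phenology_seasonal``,
    ``vpd_daily`` and the input ``tables``.  With ``config.output_dir``
    set, machine-readable CSVs are also written there.
    """
    config.validate()
    if config.simulate:
        tables = syn.generate_study(config.sim_params, seed=config.seed)
        tables["crops"] = syn.generate_crop_table(config.sim_params)
        log.info("simulated study with seed %d", config.seed)
    else:
        tables = {
            name: read_table(path, name) for name, path in sorted(config.inputs.items())
        }

    density_table = SugarDensityTable.packaged()
    results: dict = {"tables": tables, "seed": config.seed}

    # --- nectar wastage -----------------------------------------------------
    nectar = st.nectar_sugar_rates(tables["nectar"], density_table)
    agg = st.aggregate_means(nectar)
    log.info("aggregated %d nectar samples into %d cell means", len(nectar), len(agg))

    # stepwise simplification on ML fits: interaction first, then location
    terms: list[str] = ["treatment", "location", "treatment:location"]
    lrt_rows = []
    full = st.fit_lmm(agg, fixed=terms, reml=False)
    reduced = st.fit_lmm(agg, fixed=terms[:2], reml=False)
    stat, df_, p = st.lrt(full, reduced)
    lrt_rows.append({"dropped": "treatment:location", "chisq": stat, "df": df_, "p": p})
    if p > config.alpha:
        terms = terms[:2]
        main = st.fit_lmm(agg, fixed=["treatment"], reml=False)
        stat, df_, p = st.lrt(reduced, main)
        lrt_rows.append({"dropped": "location", "chisq": stat, "df": df_, "p": p})
        if p > config.alpha:
            terms = ["treatment"]
    nectar_fit = st.fit_lmm(agg, fixed=terms, reml=True)
    emm = nectar_fit.emmeans("treatment").set_index("treatment")
    nectar_est = st.wastage_ratio(
        emm.loc["accessible", "emmean"],
        emm.loc["inaccessible", "emmean"],
        comparison="accessible/inaccessible",
        method="lmm-emm-ratio",
    )
    ci = None
    if config.bootstrap > 0:
        ci = st.cluster_bootstrap(
            nectar, _marginal_ratio, cluster="day", B=config.bootstrap,
            seed=config.seed, alpha=config.alpha,
        )
    results["nectar_fit"] = nectar_fit
    results["nectar_lrt"] = pd.DataFrame(lrt_rows)
    results["nectar_emm"] = emm.reset_index()

    # --- pollen wastage -----------------------------------------------------
    pollen = tables["pollen"].copy()
    pollen["count"] = (
        pollen[["corner1", "corner2", "corner3", "corner4"]].sum(axis=1).astype(int)
    )
    pollen_fit = st.fit_count_model(pollen, fixed=("stage",), family="negbin")
    pemm = pollen_fit.emmeans("stage").set_index("stage")
    pollen_est = st.wastage_ratio(
        pemm.loc["end", "emmean"], pemm.loc["begin", "emmean"],
        comparison="end/begin anthesis", method="negbin-emm-ratio",
    )
    pci = None
    if config.bootstrap > 0:
        pci = st.cluster_bootstrap(
            pollen, _pollen_ratio, cluster="day", B=config.bootstrap,
            seed=config.seed + 1, alpha=config.alpha,
        )
    results["pollen_fit"] = pollen_fit
    results["pollen_emm"] = pemm.reset_index()

    # --- insects ------------------------------------------------------------
    transects = (
        tables["insects"]
        .groupby(["year", "site", "day", "period", "location", "transect"],
                 observed=True)["count"]
        .sum()
        .reset_index()
    )
    insect_fit = st.fit_count_model(
        transects, fixed=("location",), family="quasipoisson"
    )
    iemm = insect_fit.emmeans("location").set_index("location")
    results["insect_fit"] = insect_fit
    results["insect_emm"] = iemm.reset_index()
    results["insect_edge_interior_ratio"] = float(
        iemm.loc["edge", "emmean"] / iemm.loc["interior", "emmean"]
    )

    estimates = pd.DataFrame(
        [
            {
                "resource": "nectar sugar",
                "comparison": nectar_est.comparison,
                "percent_uncollected": nectar_est.percent,
                "ci_low": ci["ci_low"] if ci else None,
                "ci_high": ci["ci_high"] if ci else None,
                "B": config.bootstrap,
                "n_failed": ci["n_failed"] if ci else 0,
                "method": nectar_est.method,
                "seed": config.seed,
            },
            {
                "resource": "pollen",
                "comparison": pollen_est.comparison,
                "percent_uncollected": pollen_est.percent,
                "ci_low": pci["ci_low"] if pci else None,
                "ci_high": pci["ci_high"] if pci else None,
                "B": config.bootstrap,
                "n_failed": pci["n_failed"] if pci else 0,
                "method": pollen_est.method,
                "seed": config.seed,
            },
        ]
    )
    results["estimates"] = estimates

    # --- per-day budgets ----------------------------------------------------
    flowers = tables["flowers"]
    day_budgets = []
    skipped = []
    for day, nday in nectar.groupby("day", observed=True):
        fday = flowers[flowers["day"] == day]
        tday = transects[transects["day"] == day]
        rac = fday.loc[fday["kind"] == "quadrat_racemes", "count"]
        flw = fday.loc[fday["kind"] == "raceme_flowers", "count"]
        inacc = nday[nday["treatment"] == "inaccessible"]
        acc = nday[nday["treatment"] == "accessible"]
        if len(rac) == 0 or len(flw) == 0 or len(tday) == 0 or len(inacc) == 0 or len(acc) == 0:
            skipped.append(day)
            log.warning("day %s skipped in budget: missing inputs", day)
            continue
        day_budgets.append(
            bdg.day_budget(
                day=str(day),
                raceme_counts_per_m2=rac.tolist(),
                flowers_per_raceme=flw.tolist(),
                transect_counts=tday["count"].tolist(),
                secretion_uL_flower_h=float(inacc["volume_rate_uL_h"].mean()),
                secretion_ug_sugar_flower_h=float(inacc["sugar_rate_ug_h"].mean()),
                uncollected_ug_sugar_flower_h=float(acc["sugar_rate_ug_h"].mean()),
                transect_area_m2=config.transect_area_m2,
                colony_intake_g=config.colony_intake_g,
            )
        )
    if not day_budgets:
        raise ConfigError("no study day had complete budget inputs")
    results["budget_days"] = pd.DataFrame(
        [dataclasses.asdict(b) for b in day_budgets]
    )
    results["budget_pooled"] = bdg.pooled_budget(day_budgets)
    results["budget_days_skipped"] = skipped

    # --- phenology ----------------------------------------------------------
    if "crops" in tables:
        monthly = phen.monthly_bloom_area(tables["crops"])
        results["phenology_monthly"] = monthly
        results["phenology_seasonal"] = phen.seasonal_totals(monthly, config.seasons)

    # --- weather context ----------------------------------------------------
    if "weather" in tables:
        w = tables["weather"]
        results["vpd_daily"] = (
            w.groupby("day", observed=True)
            .apply(
                lambda g: daily_mean_vpd(
                    g["temperature_c"], g["relative_humidity_pct"]
                ),
                include_groups=False,
            )
            .rename("vpd_kpa")
            .reset_index()
        )

    if config.output_dir is not None:
        _write_bundle(results, Path(config.output_dir))
    return results


def _write_bundle(results: Mapping, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["estimates"].to_csv(outdir / "estimates.csv", index=False)
    results["budget_days"].to_csv(outdir / "budget_days.csv", index=False)
    pd.DataFrame([results["budget_pooled"]]).to_csv(
        outdir / "budget_pooled.csv", index=False
    )
    if "phenology_monthly" in results:
        results["phenology_monthly"].to_csv(outdir / "phenology_monthly.csv")
        results["phenology_seasonal"].to_csv(outdir / "phenology_seasonal.csv")
    if "vpd_daily" in results:
        results["vpd_daily"].to_csv(outdir / "vpd_daily.csv", index=False)
    for name, df in results["tables"].items():
        df.to_csv(outdir / f"input_{name}.csv", index=False)
    log.info("wrote result bundle to %s", outdir)
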