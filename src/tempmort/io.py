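"""CSV schemas, run configuration and the end-to-end pipeline.

All tables travel as plain CSV with fixed column sets, written with a
schema-version header comment so runs are self-describing:

* covariates: country, hottest_month_temp, coldest_month_temp, gdp_pc_ppp,
  population, mortality_rate
* responses:  country, scenario, period, dT, y_hot, y_cold
* warming:    country, scenario, period, dT  (global rows use country=GLOBAL)
* income:     country, scenario, year, gdp_pc_ppp

The synthetic generator writes exactly these schemas, so synthetic and
real-data runs are interchangeable.  ``run_pipeline`` composes the stages:
read (or simulate) inputs -> fit and cross-validate Models 1-4 for heat and
cold -> project every country per scenario x period, with and without
income-based adaptation -> aggregate globally -> trace the
warming-response curve.  Every configurable choice is echoed to the log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, models, projection, synthetic
from .config import (
    DEFAULT_PERIOD_YEARS,
    DEFAULT_PREINDUSTRIAL_OFFSET,
    ConfigError,
    SyntheticConfig,
)
from .projection import WarmingField

logger = logging.getLogger("tempmort")

SCHEMA_VERSION = "tempmort-csv-v1"
GLOBAL_ROW = "GLOBAL"

COVARIATE_COLS = [
    "country",
    "hottest_month_temp",
    "coldest_month_temp",
    "gdp_pc_ppp",
    "population",
    "mortality_rate",
]
RESPONSE_COLS = ["country", "scenario", "period", "dT", "y_hot", "y_cold"]
WARMING_COLS = ["country", "scenario", "period", "dT"]
INCOME_COLS = ["country", "scenario", "year", "gdp_pc_ppp"]


class SchemaError(ValueError):
    """Raised when an input file violates its schema or units."""


# --- country-name normalization -------------------------------------------

#: Common name variants -> ISO 3166-1 alpha-3, for real-data inputs.
COUNTRY_ALIASES = {
    "UNITED STATES": "USA",
    "UNITED STATES OF AMERICA": "USA",
    "US": "USA",
    "UNITED KINGDOM": "GBR",
    "UK": "GBR",
    "SOUTH KOREA": "KOR",
    "KOREA, REP.": "KOR",
    "CZECH REPUBLIC": "CZE",
    "CZECHIA": "CZE",
    "VIETNAM": "VNM",
    "VIET NAM": "VNM",
    "TAIWAN": "TWN",
    "MOLDOVA": "MDA",
    "RUSSIA": "RUS",
    "IRAN": "IRN",
}


def normalize_country(value: str) -> str:
    """Normalize a country identifier to an alpha-3-style code."""
    s = str(value).strip()
    if len(s) == 3 and s.isalpha():
        return s.upper()
    return COUNTRY_ALIASES.get(s.upper(), s.upper())


# --- readers / writers -----------------------------------------------------


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a CSV with the schema-version header comment (deterministic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index, float_format="%.10g", lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_covariates(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, COVARIATE_COLS, path)
    df["country"] = df["country"].map(normalize_country)
    dup = df["country"].duplicated()
    if dup.any():
        raise SchemaError(f"{path}: duplicate countries {sorted(df['country'][dup])}")
    for i, row in df.iterrows():
        if not row["gdp_pc_ppp"] > 0:
            raise SchemaError(
                f"{path}: row {i} ({row['country']}): gdp_pc_ppp must be > 0, "
                f"got {row['gdp_pc_ppp']}"
            )
        if row["population"] < 0:
            raise SchemaError(f"{path}: row {i} ({row['country']}): negative population")
        if not 0 <= row["mortality_rate"] < 1:
            raise SchemaError(
                f"{path}: row {i} ({row['country']}): mortality_rate must be in [0, 1)"
            )
        if row["hottest_month_temp"] < row["coldest_month_temp"]:
            raise SchemaError(
                f"{path}: row {i} ({row['country']}): hottest month colder than coldest"
            )
    out = df.set_index("country")
    out["log_gdp_pc"] = np.log(out["gdp_pc_ppp"])
    return out


def read_responses(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, RESPONSE_COLS, path)
    df["country"] = df["country"].map(normalize_country)
    if (df["dT"] < 0).any():
        i = int(df.index[df["dT"] < 0][0])
        raise SchemaError(f"{path}: row {i}: dT must be >= 0")
    dup = df.duplicated(["country", "scenario", "period"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate country x scenario x period rows")
    return df[RESPONSE_COLS]


def read_warming(path) -> list[WarmingField]:
    df = read_csv(path)
    _require_columns(df, WARMING_COLS, path)
    df["country"] = df["country"].map(normalize_country)
    fields = []
    for (scenario, period), grp in df.groupby(["scenario", "period"], sort=True):
        glob = grp[grp["country"] == GLOBAL_ROW]
        if len(glob) != 1:
            raise SchemaError(
                f"{path}: scenario {scenario} period {period}: need exactly one "
                f"{GLOBAL_ROW} row, found {len(glob)}"
            )
        local = grp[grp["country"] != GLOBAL_ROW]
        fields.append(
            WarmingField(
                scenario=scenario,
                period=period,
                dT=local.set_index("country")["dT"],
                global_dT=float(glob["dT"].iloc[0]),
            )
        )
    return fields


def read_income(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, INCOME_COLS, path)
    df["country"] = df["country"].map(normalize_country)
    if (df["gdp_pc_ppp"] <= 0).any():
        i = int(df.index[df["gdp_pc_ppp"] <= 0][0])
        raise SchemaError(f"{path}: row {i}: gdp_pc_ppp must be > 0")
    return df[INCOME_COLS]


def warming_to_frame(fields: list[WarmingField]) -> pd.DataFrame:
    rows = []
    for f in fields:
        rows.append({"country": GLOBAL_ROW, "scenario": f.scenario,
                     "period": f.period, "dT": f.global_dT})
        for country, dT in f.dT.items():
            rows.append({"country": country, "scenario": f.scenario,
                         "period": f.period, "dT": dT})
    return pd.DataFrame(rows, columns=WARMING_COLS)


# --- run configuration -----------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; every option has a documented default.

    Paths may be omitted when ``synthetic`` is set, in which case inputs are
    generated (and written next to the outputs for inspection).
    """

    covariates: str | None = None
    responses: str | None = None
    warming: str | None = None
    income: str | None = None
    output_dir: str = "tempmort_out"
    synthetic: bool = True
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    income_growth: float = 0.02  # synthetic annual per-capita growth rate
    loocv_unit: str = "country"  # fold unit: country | observation
    small_sample: str = "stata"  # clustered-vcov factor: stata | cr1 | none
    ci_level: float = 0.95
    quantile_family: str = "z"  # z | t (t uses G-1 df)
    weight_scheme: str = "baseline_deaths"  # | population
    period_years: dict = field(default_factory=lambda: dict(DEFAULT_PERIOD_YEARS))
    preindustrial_offset: float = DEFAULT_PREINDUSTRIAL_OFFSET
    curve_max_dT: float = 5.0
    curve_step: float = 0.1
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic_config" in raw:
            sub = raw["synthetic_config"]
            sub_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            sub_unknown = set(sub) - sub_known
            if sub_unknown:
                raise ConfigError(f"unknown synthetic_config keys: {sorted(sub_unknown)}")
            for key in ("beta_hot", "beta_cold", "hottest_range", "coldest_range",
                        "income_range", "population_range", "mortality_rate_range",
                        "sigma_country", "sigma_obs"):
                if key in sub and isinstance(sub[key], list):
                    sub[key] = tuple(sub[key])
            raw["synthetic_config"] = SyntheticConfig(**sub)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> "RunConfig":
        if self.loocv_unit not in ("country", "observation"):
            raise ConfigError(f"loocv_unit must be country|observation, got {self.loocv_unit!r}")
        if self.small_sample not in models.SMALL_SAMPLE_FACTORS:
            raise ConfigError(f"small_sample must be one of {models.SMALL_SAMPLE_FACTORS}")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must be in (0, 1)")
        if self.quantile_family not in ("z", "t"):
            raise ConfigError("quantile_family must be 'z' or 't'")
        if self.weight_scheme not in aggregation.WEIGHT_SCHEMES:
            raise ConfigError(f"weight_scheme must be one of {aggregation.WEIGHT_SCHEMES}")
        if self.curve_max_dT <= 0 or self.curve_step <= 0:
            raise ConfigError("curve grid parameters must be positive")
        if not self.synthetic:
            for name in ("covariates", "responses", "warming"):
                if getattr(self, name) is None:
                    raise ConfigError(f"non-synthetic run requires a {name} path")
        self.synthetic_config.validate()
        return self


@dataclass
class InputBundle:
    countries: pd.DataFrame
    responses: pd.DataFrame
    warming: list[WarmingField]
    income: pd.DataFrame | None


def read_tables(config: RunConfig) -> InputBundle:
    """Read and validate the input bundle, checking referential integrity."""
    countries = read_covariates(config.covariates)
    responses = read_responses(config.responses)
    warming = read_warming(config.warming)
    income = read_income(config.income) if config.income else None
    orphans = sorted(set(responses["country"]) - set(countries.index))
    if orphans:
        raise SchemaError(
            f"response table references countries without covariates: "
            f"{', '.join(orphans)}"
        )
    logger.info(
        "inputs: %d countries, %d response rows, %d warming fields",
        len(countries), len(responses), len(warming),
    )
    return InputBundle(countries, responses, warming, income)


def synthesize_inputs(config: RunConfig) -> InputBundle:
    """Generate a seeded synthetic input bundle matching the CSV schemas."""
    years = sorted({2015, 2035, *config.period_years.values(), 2100})
    world, warming, responses, income = synthetic.generate_all(
        config.synthetic_config, growth=config.income_growth, years=years
    )
    return InputBundle(world, responses, warming, income)


# --- pipeline --------------------------------------------------------------


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run the full analysis; returns (and optionally writes) all artifacts.

    Artifact keys: validation_heat, validation_cold, projections,
    missing_report, global_summary, curve, curve_adapted.
    """
    config.validate()
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        for key, value in sorted(dataclasses.asdict(config).items()):
            logger.info("config %s = %r", key, value)
        if config.synthetic:
            bundle = synthesize_inputs(config)
            if write:
                write_csv(bundle.countries.reset_index(), outdir / "covariates.csv")
                write_csv(bundle.responses, outdir / "responses.csv")
                write_csv(warming_to_frame(bundle.warming), outdir / "warming.csv")
                write_csv(bundle.income, outdir / "income.csv")
        else:
            bundle = read_tables(config)

        # fit + validate both outcomes
        tables, best = {}, {}
        for outcome in ("heat", "cold"):
            table = models.select_model(
                bundle.responses, bundle.countries, outcome,
                unit=config.loocv_unit, small_sample=config.small_sample,
            )
            tables[outcome] = table
            best[outcome] = table.attrs["best"]
            logger.info(
                "%s: selected model %d (%s), cv_rmse=%.4f",
                outcome, table.index[0], best[outcome].spec.terms,
                best[outcome].cv_rmse,
            )

        # project all scenario x period x adaptation
        proj_frames, missing_frames, summaries = [], [], []
        for f in bundle.warming:
            for adaptation in (False, True):
                period_year = config.period_years.get(f.period)
                projs = projection.project_all(
                    best["heat"], best["cold"], bundle.countries, f,
                    adaptation=adaptation, income_paths=bundle.income,
                    period_year=period_year, level=config.ci_level,
                    family=config.quantile_family,
                )
                proj_frames.append(projection.projections_frame(projs))
                mr = projection.missing_report(projs)
                if not mr.empty:
                    missing_frames.append(mr)
                s = aggregation.global_rate_change(
                    projs, bundle.countries, best["heat"], best["cold"],
                    config.weight_scheme, config.ci_level, config.quantile_family,
                )
                summaries.append(dataclasses.asdict(s))
        projections_df = pd.concat(proj_frames, ignore_index=True)
        missing_df = (
            pd.concat(missing_frames, ignore_index=True)
            if missing_frames
            else pd.DataFrame(columns=["country", "scenario", "period", "adaptation", "reason"])
        )
        summary_df = pd.DataFrame(summaries).drop(columns=["excess_deaths"])

        # warming-response curves
        ratios = aggregation.pattern_ratios(bundle.warming)
        grid = np.round(
            np.arange(0.0, config.curve_max_dT + 1e-9, config.curve_step), 10
        )
        curve = aggregation.warming_response_curve(
            best["heat"], best["cold"], bundle.countries, ratios,
            global_dT_grid=grid, weight_scheme=config.weight_scheme,
            level=config.ci_level, family=config.quantile_family,
            preindustrial_offset=config.preindustrial_offset,
        )
        curve_adapted = aggregation.warming_response_curve(
            best["heat"], best["cold"], bundle.countries, ratios,
            global_dT_grid=grid, adaptation=True, income_paths=bundle.income,
            period_year=config.period_years["end"],
            weight_scheme=config.weight_scheme, level=config.ci_level,
            family=config.quantile_family,
            preindustrial_offset=config.preindustrial_offset,
        )

        artifacts = {
            "validation_heat": tables["heat"].drop(columns=[], errors="ignore"),
            "validation_cold": tables["cold"],
            "fit_heat": best["heat"],
            "fit_cold": best["cold"],
            "projections": projections_df,
            "missing_report": missing_df,
            "global_summary": summary_df,
            "curve": curve,
            "curve_adapted": curve_adapted,
            "pattern_ratios": ratios,
        }
        if write:
            write_csv(tables["heat"].reset_index(), outdir / "validation_heat.csv")
            write_csv(tables["cold"].reset_index(), outdir / "validation_cold.csv")
            write_csv(projections_df, outdir / "projections.csv")
            write_csv(missing_df, outdir / "missing_report.csv")
            write_csv(summary_df, outdir / "global_summary.csv")
            write_csv(curve, outdir / "curve.csv")
            write_csv(curve_adapted, outdir / "curve_adapted.csv")
            write_csv(ratios.reset_index().rename(columns={"index": "country"}),
                      outdir / "pattern_ratios.csv")
        return artifacts
    finally:
        if write:
            logger.removeHandler(handler)
            handler.close()
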