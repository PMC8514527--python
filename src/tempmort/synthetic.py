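"""Synthetic toy worlds for end-to-end testing of the damage-function pipeline.

Every input the pipeline consumes can be generated here from a single seeded
configuration: country covariates (climatology, income, population, baseline
mortality), per-country warming fields pattern-scaled from a global-mean
table, response tables drawn from known damage-function coefficients with
country-clustered noise, small gridded rasters consistent with the country
climatologies, and compound-growth income paths.  Ground truth is known by
construction, so estimator bias, CI coverage and model selection can all be
measured directly.

Sampling laws (deliberately simple, full-support):

* hottest/coldest month temperatures uniform on configured intervals,
  redrawn jointly until hottest > coldest;
* per-capita income log-uniform between configured bounds;
* country warming ratio r_c lognormal with mean 1 and log-sd
  ``pattern_spread`` (r_c > 0; country dT = r_c x global dT);
* response noise = country random effect + i.i.d. observation noise, both
  normal — the clustering the cluster-robust estimator must absorb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climatology import MONTH_COLS
from .config import PERIODS, SCENARIOS, ConfigError, SyntheticConfig
from .models import MODEL_TERMS, ModelSpec, build_design
from .projection import WarmingField

__all__ = [
    "country_codes",
    "generate_world",
    "generate_warming",
    "generate_response_table",
    "generate_grids",
    "generate_income_paths",
    "generate_all",
]


def country_codes(n: int) -> list[str]:
    """Deterministic ISO-alpha-3-style synthetic codes: SAA, SAB, ..."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n > len(letters) ** 2:
        raise ConfigError(f"at most {len(letters)**2} synthetic countries supported")
    return ["S" + letters[i // 26] + letters[i % 26] for i in range(n)]


def generate_world(config: SyntheticConfig) -> pd.DataFrame:
    """Country covariate table: one row per synthetic country.

    Columns: hottest_month_temp, coldest_month_temp, gdp_pc_ppp, log_gdp_pc,
    population, mortality_rate; indexed by country code.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    hot = rng.uniform(*config.hottest_range, size=n)
    cold = rng.uniform(*config.coldest_range, size=n)
    # enforce hottest > coldest by jointly redrawing offending countries
    bad = cold >= hot
    while bad.any():
        hot[bad] = rng.uniform(*config.hottest_range, size=int(bad.sum()))
        cold[bad] = rng.uniform(*config.coldest_range, size=int(bad.sum()))
        bad = cold >= hot
    gdp = np.exp(rng.uniform(*np.log(config.income_range), size=n))
    pop = np.exp(rng.uniform(*np.log(config.population_range), size=n))
    mort = rng.uniform(*config.mortality_rate_range, size=n)
    world = pd.DataFrame(
        {
            "hottest_month_temp": hot,
            "coldest_month_temp": cold,
            "gdp_pc_ppp": gdp,
            "log_gdp_pc": np.log(gdp),
            "population": pop,
            "mortality_rate": mort,
        },
        index=pd.Index(country_codes(n), name="country"),
    )
    return world


def pattern_ratio_draw(rng: np.random.Generator, n: int, spread: float) -> np.ndarray:
    """Country warming ratios: lognormal with E[r] = 1, log-sd = spread."""
    if spread == 0:
        return np.ones(n)
    return np.exp(rng.normal(-0.5 * spread**2, spread, size=n))


def generate_warming(
    world: pd.DataFrame,
    scenarios=SCENARIOS,
    periods=PERIODS,
    global_dT_table: dict[tuple[str, str], float] | None = None,
    pattern_spread: float = 0.15,
    seed: int = 42,
) -> list[WarmingField]:
    """Pattern-scaled warming fields: country dT = r_c x global dT.

    One ratio r_c > 0 is drawn per country and shared across all
    scenario x period fields, so warming is perfectly correlated across
    scenarios within a country, as with a single downscaling pattern.
    Global dT must be positive and strictly increasing across the RCP
    ladder within each period.
    """
    if global_dT_table is None:
        from .config import DEFAULT_GLOBAL_DT

        global_dT_table = DEFAULT_GLOBAL_DT
    for period in periods:
        vals = [global_dT_table[(s, period)] for s in scenarios]
        if min(vals) <= 0:
            raise ConfigError(f"global dT must be positive, got {vals} for {period}")
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ConfigError(
                f"global dT must increase strictly across {scenarios} in period "
                f"{period!r}, got {vals}"
            )
    if pattern_spread < 0:
        raise ConfigError("pattern_spread must be nonnegative")
    rng = np.random.default_rng(seed)
    ratios = pd.Series(
        pattern_ratio_draw(rng, len(world), pattern_spread), index=world.index
    )
    fields = []
    for scenario in scenarios:
        for period in periods:
            g = float(global_dT_table[(scenario, period)])
            fields.append(
                WarmingField(
                    scenario=scenario,
                    period=period,
                    dT=ratios * g,
                    global_dT=g,
                )
            )
    return fields


def generate_response_table(
    world: pd.DataFrame,
    warming: list[WarmingField],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Response table drawn from the configured true coefficients.

    One row per country x scenario x period with columns country, scenario,
    period, dT, y_hot, y_cold.  Each outcome is its specification's exact
    mean at the row covariates plus a country random effect (shared by all
    of the country's rows; SD ``sigma_country``) plus i.i.d. observation
    noise (SD ``sigma_obs``).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    for f in warming:
        for country in f.countries():
            if country not in world.index:
                raise ConfigError(f"missing covariates for country {country}")
            dT = f.dT.get(country)
            if dT is None or not np.isfinite(dT):
                raise ConfigError(f"missing warming for country {country}")
            rows.append(
                {"country": country, "scenario": f.scenario, "period": f.period,
                 "dT": float(dT)}
            )
    obs = pd.DataFrame(rows)
    dup = obs.duplicated(["country", "scenario", "period"])
    if dup.any():
        raise ConfigError("duplicate country x scenario x period rows in warming input")
    X_hot = build_design(obs, world, ModelSpec("heat", MODEL_TERMS[4]))
    X_cold = build_design(obs, world, ModelSpec("cold", MODEL_TERMS[3]))
    mean_hot = X_hot @ np.asarray(config.beta_hot)
    mean_cold = X_cold @ np.asarray(config.beta_cold)
    sc_hot, sc_cold = config.sigma_country_pair
    so_hot, so_cold = config.sigma_obs_pair
    u_hot = pd.Series(rng.normal(0, sc_hot, len(world)), index=world.index)
    u_cold = pd.Series(rng.normal(0, sc_cold, len(world)), index=world.index)
    countries = obs["country"]
    obs["y_hot"] = (
        mean_hot + u_hot.loc[countries].to_numpy() + rng.normal(0, so_hot, len(obs))
    )
    obs["y_cold"] = (
        mean_cold + u_cold.loc[countries].to_numpy() + rng.normal(0, so_cold, len(obs))
    )
    return obs


def _monthly_cycle(hot: float, cold: float) -> np.ndarray:
    """Sinusoidal 12-month cycle with minimum ``cold`` in January and
    maximum ``hot`` in July (northern-hemisphere convention)."""
    m = np.arange(12)
    mean, amp = (hot + cold) / 2.0, (hot - cold) / 2.0
    return mean - amp * np.cos(2 * np.pi * m / 12.0)


def generate_grids(
    world: pd.DataFrame,
    cells_per_country: int = 4,
    seed: int = 42,
    include_zero_pop_cells: bool = False,
) -> pd.DataFrame:
    """Toy raster whose population-weighted aggregation reproduces ``world``.

    Each country gets ``cells_per_country`` populated cells.  Cell monthly
    temperatures are the country's sinusoidal cycle (coldest month January,
    hottest July, endpoints equal to the country's coldest/hottest covariate)
    plus cell perturbations whose population-weighted mean is exactly zero —
    so the climatology module recovers the country record to rounding error.
    Optionally appends one zero-population cell per country, which weighted
    aggregation must ignore.
    """
    if cells_per_country < 1:
        raise ConfigError("cells_per_country must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for lat, (country, rec) in enumerate(world.iterrows()):
        cycle = _monthly_cycle(rec["hottest_month_temp"], rec["coldest_month_temp"])
        pops = rng.uniform(0.2, 1.0, size=cells_per_country)
        pops = pops / pops.sum() * rec["population"]
        delta = rng.normal(0, 1.5, size=(cells_per_country, 12))
        delta -= np.average(delta, axis=0, weights=pops)  # zero weighted mean
        temps = cycle[None, :] + delta
        df = pd.DataFrame(temps, columns=MONTH_COLS)
        df.insert(0, "pop", pops)
        df.insert(0, "country", country)
        df.insert(0, "lon_idx", np.arange(cells_per_country))
        df.insert(0, "lat_idx", lat)
        if include_zero_pop_cells:
            ghost = df.iloc[[0]].copy()
            ghost["lon_idx"] = cells_per_country
            ghost["pop"] = 0.0
            ghost[MONTH_COLS] = cycle + rng.normal(0, 10.0, size=12)
            df = pd.concat([df, ghost], ignore_index=True)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_income_paths(
    world: pd.DataFrame,
    per_country_growth,
    years,
    scenario: str = "SSP3",
    base_year: int = 2015,
) -> pd.DataFrame:
    """Compound-growth income paths: gdp(y) = gdp_base * (1+g)^(y-base_year).

    ``per_country_growth`` is a scalar annual growth rate or a mapping
    country -> rate; rates must exceed -1 (incomes stay positive).
    """
    if np.isscalar(per_country_growth):
        growth = pd.Series(float(per_country_growth), index=world.index)
    else:
        growth = pd.Series(per_country_growth, dtype=float).reindex(world.index)
        if growth.isna().any():
            bad = sorted(growth.index[growth.isna()])
            raise ConfigError(f"missing growth rate for countries: {', '.join(bad)}")
    if not np.isfinite(growth).all() or (growth <= -1).any():
        raise ConfigError("growth rates must be finite and > -1")
    years = np.asarray(list(years), dtype=float)
    rows = []
    for country, g in growth.items():
        base = float(world.loc[country, "gdp_pc_ppp"])
        for y in years:
            rows.append(
                {
                    "country": country,
                    "scenario": scenario,
                    "year": y,
                    "gdp_pc_ppp": base * (1.0 + g) ** (y - base_year),
                }
            )
    return pd.DataFrame(rows)


def generate_all(
    config: SyntheticConfig,
    growth: float = 0.02,
    years=(2015, 2035, 2055, 2075, 2090, 2100),
):
    """World, warming fields, response table and income paths in one call.

    All randomness derives from ``config.seed`` (world: seed, warming:
    seed+2, responses: seed+1), so identical configs give identical bundles.
    """
    world = generate_world(config)
    warming = generate_warming(
        world,
        global_dT_table=config.global_dt,
        pattern_spread=config.pattern_spread,
        seed=config.seed + 2,
    )
    responses = generate_response_table(world, warming, config)
    income = generate_income_paths(world, growth, years)
    return world, warming, responses, income
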