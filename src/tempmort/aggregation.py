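"""Global aggregation of country damage projections.

Country percent mortality-rate changes are combined into a global percent
change as a weighted mean.  The natural weights for a rate change are each
country's share of expected baseline deaths (mortality_rate x population);
population shares are available as a sensitivity.  Because every country's
projection is a linear function x_c'b of the same fitted coefficient
vector, the weighted mean is itself linear with design x_glob = sum w_c x_c,
and its delta-method variance x_glob' V x_glob propagates the perfect
cross-country correlation induced by shared coefficients (averaging
per-country variances would understate it).  Heat and cold variances are
added (separate fits, treated as independent).

The warming-response curve traces that global aggregate as a continuous
function of global-mean warming, using pattern-scaling ratios r_c (country
warming per degree of global warming) estimated from discrete
scenario x period fields by a no-intercept regression of country dT on
global dT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FittedDamageModel
from .projection import (
    CountryProjection,
    WarmingField,
    _quantile,
    project_all,
    quad_form_variance,
)

WEIGHT_SCHEMES = ("baseline_deaths", "population")


class AggregationError(ValueError):
    """Raised for ill-posed aggregation requests."""


@dataclass
class GlobalSummary:
    """Weighted global mortality-rate change for one scenario x period."""

    scenario: str
    period: str
    adaptation: bool
    y_hot: float
    y_cold: float
    y_net: float
    ci_low: float
    ci_high: float
    weight_scheme: str
    excess_deaths: float | None = None


def _weights(countries: list, country_records: pd.DataFrame, scheme: str) -> pd.Series:
    if scheme not in WEIGHT_SCHEMES:
        raise AggregationError(f"weight_scheme must be one of {WEIGHT_SCHEMES}")
    recs = country_records.loc[countries]
    if scheme == "baseline_deaths":
        w = recs["mortality_rate"] * recs["population"]
    else:
        w = recs["population"].astype(float)
    total = float(w.sum())
    if total <= 0:
        raise AggregationError("aggregation weights sum to zero")
    return w / total


def global_rate_change(
    projections: list[CountryProjection],
    country_records: pd.DataFrame,
    fit_hot: FittedDamageModel | None = None,
    fit_cold: FittedDamageModel | None = None,
    weight_scheme: str = "baseline_deaths",
    level: float = 0.95,
    family: str = "z",
) -> GlobalSummary:
    """Aggregate country projections to a global percent rate change.

    Missing projections are excluded; weights are renormalized over the
    included countries.  The CI needs the fitted models (for their
    coefficient covariances); with fits omitted or lacking vcov the summary
    carries NaN bounds.
    """
    valid = [p for p in projections if not p.missing]
    if not valid:
        raise AggregationError("no non-missing projections to aggregate")
    w = _weights([p.country for p in valid], country_records, weight_scheme)
    wv = w.to_numpy(float)
    y_hot = float(np.dot(wv, [p.y_hot for p in valid]))
    y_cold = float(np.dot(wv, [p.y_cold for p in valid]))
    y_net = y_hot + y_cold
    ci_low = ci_high = np.nan
    if (
        fit_hot is not None and fit_cold is not None
        and fit_hot.vcov is not None and fit_cold.vcov is not None
        and all(p.x_hot is not None for p in valid)
    ):
        x_glob_hot = np.sum([wi * p.x_hot for wi, p in zip(wv, valid)], axis=0)
        x_glob_cold = np.sum([wi * p.x_cold for wi, p in zip(wv, valid)], axis=0)
        var = quad_form_variance(fit_hot.vcov, x_glob_hot) + quad_form_variance(
            fit_cold.vcov, x_glob_cold
        )
        g_max = max(fit_hot.n_clusters, fit_cold.n_clusters)
        df = g_max - 1 if g_max > 1 else None
        half = _quantile(level, family, df) * math.sqrt(var)
        ci_low, ci_high = y_net - half, y_net + half
    first = valid[0]
    return GlobalSummary(
        scenario=first.scenario,
        period=first.period,
        adaptation=first.adaptation,
        y_hot=y_hot,
        y_cold=y_cold,
        y_net=y_net,
        ci_low=ci_low,
        ci_high=ci_high,
        weight_scheme=weight_scheme,
    )


def excess_deaths(global_rate_change_pct: float, projected_deaths: float) -> float:
    """Excess deaths implied by a percent mortality-rate change.

    ``projected_deaths`` is the counterfactual number of deaths in the
    target year (e.g. from demographic projections); the rate change scales
    it: count = (pct/100) x deaths.
    """
    if projected_deaths < 0:
        raise AggregationError("projected deaths must be nonnegative")
    return global_rate_change_pct / 100.0 * projected_deaths


def excess_deaths_by_country(
    pct_by_country: pd.Series, deaths_by_country: pd.Series
) -> float:
    """Country-resolved variant: sum of per-country excess deaths."""
    if (deaths_by_country < 0).any():
        raise AggregationError("projected deaths must be nonnegative")
    common = pct_by_country.index.intersection(deaths_by_country.index)
    return float(
        (pct_by_country.loc[common] / 100.0 * deaths_by_country.loc[common]).sum()
    )


def pattern_ratios(warming_fields: list[WarmingField]) -> pd.Series:
    """Per-country warming ratios r_c from discrete scenario x period fields.

    r_c is the no-intercept least-squares slope of country dT on global dT
    across fields (r_c = sum dT_c*g / sum g^2).  A country observed in only
    one field gets the single-point ratio, with a warning.
    """
    usable = [f for f in warming_fields if f.global_dT > 0]
    if len(usable) < 2:
        raise AggregationError("need >= 2 warming fields with positive global dT")
    g = np.array([f.global_dT for f in usable])
    dt = pd.DataFrame({i: f.dT for i, f in enumerate(usable)})
    ratios = {}
    for country, row in dt.iterrows():
        mask = row.notna().to_numpy()
        n_pts = int(mask.sum())
        if n_pts == 0:
            continue
        if n_pts == 1:
            warnings.warn(
                f"pattern ratio for {country} from a single scenario point",
                stacklevel=2,
            )
        gv = g[mask]
        ratios[country] = float(np.dot(row.to_numpy(float)[mask], gv) / np.dot(gv, gv))
    out = pd.Series(ratios, name="pattern_ratio")
    if (out <= 0).any():
        raise AggregationError("pattern ratios must be positive")
    return out


def warming_response_curve(
    fit_hot: FittedDamageModel,
    fit_cold: FittedDamageModel,
    country_records: pd.DataFrame,
    ratios: pd.Series,
    global_dT_grid=None,
    adaptation: bool = False,
    income_paths: pd.DataFrame | None = None,
    period_year: float | None = None,
    weight_scheme: str = "baseline_deaths",
    level: float = 0.95,
    family: str = "z",
    preindustrial_offset: float = 0.0,
) -> pd.DataFrame:
    """Global mortality response as a function of global-mean warming.

    For each grid value g (degC vs 2001-2020): country dT = r_c*g, project
    all countries, aggregate.  Columns: global_dT, global_dT_preindustrial,
    y_hot, y_cold, y_net, ci_low, ci_high.  The curve passes through the
    origin by the no-intercept construction.
    """
    if global_dT_grid is None:
        global_dT_grid = np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)
    grid = np.asarray(list(global_dT_grid), float)
    if (grid < 0).any():
        raise AggregationError("global warming grid values must be >= 0")
    rows = []
    for g in grid:
        field = WarmingField(
            scenario="curve", period="curve", dT=ratios * g, global_dT=float(g)
        )
        projections = project_all(
            fit_hot, fit_cold, country_records, field,
            adaptation=adaptation, income_paths=income_paths,
            period_year=period_year, level=level, family=family,
        )
        s = global_rate_change(
            projections, country_records, fit_hot, fit_cold,
            weight_scheme, level, family,
        )
        rows.append(
            {
                "global_dT": float(g),
                "global_dT_preindustrial": float(g) + preindustrial_offset,
                "y_hot": s.y_hot,
                "y_cold": s.y_cold,
                "y_net": s.y_net,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        )
    return pd.DataFrame(rows)
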