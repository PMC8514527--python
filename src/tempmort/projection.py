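"""Country-level projection of mortality-rate changes under warming.

Evaluates fitted heat and cold damage functions for each country at its
projected warming dT, with or without income-based adaptation.  Adaptation
replaces the current log per-capita income in the heat model's triple
interaction with the income projected for the period midpoint year; the
cold model carries no income term and is unaffected.  The net change is
y_net = y_hot + y_cold, and 95% intervals come from the delta method: a
projection is linear in the coefficients, so Var(x'b) = x'Vx exactly, with
V the cluster-robust coefficient covariance.  Heat and cold are fit
separately, so their coefficient vectors are treated as independent and the
net variance is the sum.  dT itself is treated as fixed (climate-model
spread is not propagated).

Countries lacking warming or covariate data yield explicit "missing" rows
with a reason — never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import FittedDamageModel, design_row


class ProjectionError(ValueError):
    """Raised for ill-posed projection requests."""


@dataclass
class WarmingField:
    """Per-country warming for one scenario x period.

    ``dT`` maps country -> warming (degC vs the 2001-2020 mean); countries
    without data are simply absent (or NaN), never coerced to zero.
    ``global_dT`` is the global-mean warming on the same baseline;
    ``global_dT_preindustrial`` additionally includes the
    preindustrial-to-present offset.
    """

    scenario: str
    period: str
    dT: pd.Series
    global_dT: float
    global_dT_preindustrial: float | None = None

    def __post_init__(self):
        self.dT = pd.Series(self.dT, dtype=float)
        finite = self.dT.dropna()
        if not np.isfinite(finite).all():
            raise ProjectionError("country dT values must be finite or absent")

    def countries(self) -> list:
        return list(self.dT.dropna().index)


@dataclass
class CountryProjection:
    """Projected percent mortality-rate change for one country x scenario x period."""

    country: str
    scenario: str
    period: str
    adaptation: bool
    y_hot: float = np.nan
    y_cold: float = np.nan
    y_net: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    x_hot: np.ndarray | None = field(default=None, repr=False)
    x_cold: np.ndarray | None = field(default=None, repr=False)
    missing: bool = False
    reason: str | None = None


def _quantile(level: float, family: str, df: int | None) -> float:
    if not 0 < level < 1:
        raise ProjectionError(f"level must be in (0,1), got {level}")
    q = (1 + level) / 2
    if family == "z":
        return float(stats.norm.ppf(q))
    if family == "t":
        if not df or df < 1:
            raise ProjectionError("t quantiles need positive degrees of freedom")
        return float(stats.t.ppf(q, df))
    raise ProjectionError(f"quantile family must be 'z' or 't', got {family!r}")


def quad_form_variance(vcov: np.ndarray, x: np.ndarray) -> float:
    """x'Vx with a symmetry/PSD sanity check (tiny negatives clipped to 0)."""
    v = float(x @ vcov @ x)
    if v < 0:
        scale = float(np.abs(vcov).max()) * float(x @ x) + 1e-300
        if v < -1e-8 * scale:
            raise ProjectionError("coefficient covariance is not positive semidefinite")
        v = 0.0
    return v


def projection_interval(
    fit: FittedDamageModel,
    design_vector: np.ndarray,
    level: float = 0.95,
    family: str = "z",
) -> tuple[float, float]:
    """Delta-method CI for the linear prediction x'beta."""
    if fit.vcov is None:
        raise ProjectionError(
            "fit has no coefficient covariance; intervals unavailable"
        )
    x = np.asarray(design_vector, float)
    point = float(x @ fit.beta)
    df = fit.n_clusters - 1 if fit.n_clusters else None
    half = _quantile(level, family, df) * math.sqrt(quad_form_variance(fit.vcov, x))
    return point - half, point + half


def project_country(
    fit_hot: FittedDamageModel,
    fit_cold: FittedDamageModel,
    record: pd.Series,
    dT: float,
    adaptation: bool = False,
    income_at_period: float | None = None,
    level: float = 0.95,
    family: str = "z",
) -> CountryProjection:
    """Project one country's heat/cold/net percent mortality-rate change.

    ``record`` is a country row with hottest_month_temp, coldest_month_temp,
    gdp_pc_ppp.  With ``adaptation`` the heat design uses
    log(income_at_period) instead of log(current income).
    """
    country = str(record.name) if record.name is not None else str(record.get("country"))
    proj = CountryProjection(country, "", "", adaptation)
    needed = ["hottest_month_temp", "coldest_month_temp", "gdp_pc_ppp"]
    absent = [c for c in needed if c not in record.index or pd.isna(record[c])]
    if dT is None or (isinstance(dT, float) and not np.isfinite(dT)):
        proj.missing, proj.reason = True, "no warming projection"
        return proj
    if absent:
        proj.missing, proj.reason = True, f"missing covariates: {', '.join(absent)}"
        return proj
    if dT < 0:
        raise ProjectionError(f"dT must be >= 0, got {dT} for {country}")
    if adaptation:
        if income_at_period is None or income_at_period <= 0:
            proj.missing, proj.reason = True, "no projected income for adaptation"
            return proj
        log_gdp = math.log(income_at_period)
    else:
        log_gdp = math.log(float(record["gdp_pc_ppp"]))
    x_hot = design_row(dT, float(record["hottest_month_temp"]), log_gdp, fit_hot.spec.terms)
    x_cold = design_row(dT, float(record["coldest_month_temp"]), log_gdp, fit_cold.spec.terms)
    y_hot = float(x_hot @ fit_hot.beta)
    y_cold = float(x_cold @ fit_cold.beta)
    proj.y_hot, proj.y_cold, proj.y_net = y_hot, y_cold, y_hot + y_cold
    proj.x_hot, proj.x_cold = x_hot, x_cold
    if fit_hot.vcov is not None and fit_cold.vcov is not None:
        var_net = quad_form_variance(fit_hot.vcov, x_hot) + quad_form_variance(
            fit_cold.vcov, x_cold
        )
        g_max = max(fit_hot.n_clusters, fit_cold.n_clusters)
        df = g_max - 1 if g_max > 1 else None
        half = _quantile(level, family, df) * math.sqrt(var_net)
        proj.ci_low, proj.ci_high = proj.y_net - half, proj.y_net + half
    return proj


def income_at_year(income_paths: pd.DataFrame, country: str, year: float) -> float | None:
    """Per-capita income for a country at a year, linearly interpolated
    between path nodes (constant extrapolation outside the node range)."""
    path = income_paths[income_paths["country"] == country]
    if path.empty:
        return None
    path = path.sort_values("year")
    return float(np.interp(year, path["year"].to_numpy(float),
                           path["gdp_pc_ppp"].to_numpy(float)))


def project_all(
    fit_hot: FittedDamageModel,
    fit_cold: FittedDamageModel,
    country_records: pd.DataFrame,
    warming_field: WarmingField,
    adaptation: bool = False,
    income_paths: pd.DataFrame | None = None,
    period_year: float | None = None,
    level: float = 0.95,
    family: str = "z",
) -> list[CountryProjection]:
    """Project every country of a warming field.

    Returns one :class:`CountryProjection` per country appearing in either
    the covariate table or the warming field; rows without the data needed
    are flagged missing with a reason.  Use :func:`projections_frame` for a
    tabular view and :func:`missing_report` for the side report.
    """
    if adaptation and income_paths is not None and period_year is None:
        raise ProjectionError("adaptation with income paths requires period_year")
    all_countries = sorted(set(country_records.index) | set(warming_field.countries()))
    shared = set(country_records.index) & set(warming_field.countries())
    if not shared:
        raise ProjectionError(
            "no overlap between covariate countries and warming-field countries"
        )
    out = []
    for country in all_countries:
        if country not in country_records.index:
            p = CountryProjection(country, warming_field.scenario,
                                  warming_field.period, adaptation,
                                  missing=True, reason="no covariates")
            out.append(p)
            continue
        record = country_records.loc[country]
        dT = warming_field.dT.get(country, np.nan)
        income = None
        if adaptation:
            if income_paths is not None:
                income = income_at_year(income_paths, country, period_year)
            else:  # no paths supplied: adaptation at unchanged income
                income = float(record["gdp_pc_ppp"])
        p = project_country(fit_hot, fit_cold, record, float(dT) if pd.notna(dT) else np.nan,
                            adaptation, income, level, family)
        p.scenario, p.period = warming_field.scenario, warming_field.period
        out.append(p)
    return out


def projections_frame(projections: list[CountryProjection]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a projection list, missing rows included."""
    return pd.DataFrame(
        [
            {
                "country": p.country,
                "scenario": p.scenario,
                "period": p.period,
                "adaptation": p.adaptation,
                "y_hot": p.y_hot,
                "y_cold": p.y_cold,
                "y_net": p.y_net,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "missing": p.missing,
            }
            for p in projections
        ]
    )


def missing_report(projections: list[CountryProjection]) -> pd.DataFrame:
    """Countries that could not be projected, with reasons."""
    return pd.DataFrame(
        [
            {"country": p.country, "scenario": p.scenario, "period": p.period,
             "adaptation": p.adaptation, "reason": p.reason}
            for p in projections
            if p.missing
        ]
    )
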