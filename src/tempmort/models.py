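"""Damage-function estimation for temperature-related mortality.

The response data are percent changes in heat- (or cold-) related mortality
projected per country x emissions scenario x period.  Four nested
specifications explain that variation as a function of country-level warming
dT, its square, and interactions with the country's extreme-month
climatology and log income:

    Model 1:  y = b1*dT
    Model 2:  y = b1*dT + b2*dT^2
    Model 3:  y = ... + b3*dT*ExtremeMonthTemp
    Model 4:  y = ... + b4*dT*ExtremeMonthTemp*log(GDPpc)

No specification has an intercept: zero warming must imply zero damage, the
defining constraint of a damage function.  Heat models interact with the
hottest-month mean temperature, cold models with the coldest-month mean.
Standard errors are clustered at the country level (sandwich estimator),
since the 8 scenario-period observations of one country share the same
underlying epidemiological response function.  Model choice is by
leave-one-out cross-validation, with country-level folds by default because
the purpose of the fit is extrapolation to unseen countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .config import (
    REFERENCE_COLD_BETA,
    REFERENCE_COLD_SE,
    REFERENCE_HEAT_BETA,
    REFERENCE_HEAT_SE,
)

TERMS = ("T", "T2", "TxM", "TxMxG")

#: Nested term sets of the four candidate specifications.
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("T",),
    2: ("T", "T2"),
    3: ("T", "T2", "TxM"),
    4: ("T", "T2", "TxM", "TxMxG"),
}

SMALL_SAMPLE_FACTORS = ("stata", "cr1", "none")


class FitError(ValueError):
    """Raised for ill-posed estimation problems (rank deficiency, too few clusters)."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate damage-function specification.

    outcome is "heat" or "cold"; terms is an ordered subset of
    ``("T", "T2", "TxM", "TxMxG")`` where M is the hottest- (heat) or
    coldest- (cold) month mean temperature and G is log per-capita GDP.
    """

    outcome: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if self.outcome not in ("heat", "cold"):
            raise FitError(f"outcome must be 'heat' or 'cold', got {self.outcome!r}")
        if not self.terms:
            raise FitError("spec needs at least one term")
        unknown = set(self.terms) - set(TERMS)
        if unknown:
            raise FitError(f"unknown terms {sorted(unknown)}; allowed: {TERMS}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def uses_income(self) -> bool:
        return "TxMxG" in self.terms


def candidate_specs(outcome: str) -> list[ModelSpec]:
    """The nested Models 1-4 for one outcome."""
    return [ModelSpec(outcome, MODEL_TERMS[i]) for i in (1, 2, 3, 4)]


def design_row(dT: float, extreme_temp: float, log_gdp: float, terms) -> np.ndarray:
    """Evaluate one design row at given warming, extreme-month temp and log income."""
    cols = {
        "T": dT,
        "T2": dT * dT,
        "TxM": dT * extreme_temp,
        "TxMxG": dT * extreme_temp * log_gdp,
    }
    return np.array([cols[t] for t in terms], dtype=float)


def build_design(
    observations: pd.DataFrame,
    country_records: pd.DataFrame,
    spec: ModelSpec,
    log_gdp_override: pd.Series | None = None,
) -> np.ndarray:
    """Design matrix aligned to ``observations`` rows.

    ``observations`` needs columns country, dT; ``country_records`` is indexed
    by country with hottest_month_temp, coldest_month_temp, gdp_pc_ppp.
    ``log_gdp_override`` (indexed by country) substitutes projected incomes
    for the income interaction, used for income-based adaptation.
    """
    temp_col = "hottest_month_temp" if spec.outcome == "heat" else "coldest_month_temp"
    missing = set(observations["country"]) - set(country_records.index)
    if missing:
        raise FitError(
            f"missing covariates for countries: {', '.join(sorted(missing))}"
        )
    recs = country_records.loc[observations["country"]]
    for col in (temp_col, "gdp_pc_ppp"):
        if recs[col].isna().any():
            bad = sorted(recs.index[recs[col].isna()].unique())
            raise FitError(f"missing {col} for countries: {', '.join(bad)}")
    dT = observations["dT"].to_numpy(float)
    m = recs[temp_col].to_numpy(float)
    if log_gdp_override is not None:
        log_g = log_gdp_override.loc[observations["country"]].to_numpy(float)
    else:
        log_g = np.log(recs["gdp_pc_ppp"].to_numpy(float))
    cols = {"T": dT, "T2": dT**2, "TxM": dT * m, "TxMxG": dT * m * log_g}
    return np.column_stack([cols[t] for t in spec.terms])


def _check_rank(X: np.ndarray, terms) -> None:
    """Raise naming the dependent columns if X is rank deficient."""
    n, k = X.shape
    if n < k:
        raise FitError(f"need at least as many rows ({n}) as columns ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
        dependent = [terms[piv[i]] for i in range(k) if i >= rank or diag[i] <= tol]
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear columns: {sorted(set(dependent))}"
        )


def cluster_robust_vcov(
    X: np.ndarray,
    residuals: np.ndarray,
    cluster_ids: np.ndarray,
    small_sample: str = "stata",
) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of the OLS coefficients.

    small_sample selects the finite-sample factor applied to the plain
    sandwich: "stata" = [G/(G-1)]*[(n-1)/(n-k)] (the convention of the
    reference tables; identical to the statsmodels default), "cr1" = G/(G-1),
    "none" = 1.
    """
    if small_sample not in SMALL_SAMPLE_FACTORS:
        raise FitError(f"small_sample must be one of {SMALL_SAMPLE_FACTORS}")
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    groups = pd.unique(cluster_ids)
    G = len(groups)
    meat = np.zeros((k, k))
    for g in groups:
        sel = cluster_ids == g
        s = X[sel].T @ residuals[sel]
        meat += np.outer(s, s)
    V = bread @ meat @ bread
    if small_sample == "stata":
        # max() guards the exactly-determined n == k case (V is ~0 there)
        V = V * (G / (G - 1)) * ((n - 1) / max(n - k, 1))
    elif small_sample == "cr1":
        V = V * (G / (G - 1))
    return (V + V.T) / 2.0


@dataclass(eq=False)  # identity equality: fields hold arrays
class FittedDamageModel:
    """A fitted no-intercept damage function with clustered uncertainty."""

    spec: ModelSpec
    beta: np.ndarray
    vcov: np.ndarray | None
    n_obs: int
    n_clusters: int
    adj_r2: float = np.nan
    adj_r2_centered: float = np.nan
    F: float = np.nan
    rmse: float = np.nan
    cv_rmse: float = np.nan
    cv_mae: float = np.nan
    cv_pseudo_r2: float = np.nan
    residuals: np.ndarray | None = None
    X: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    cluster_ids: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, float)) @ self.beta

    @property
    def se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(len(self.beta), np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def coef_table(self) -> pd.DataFrame:
        """Coefficients, clustered SEs, t (on G-1 df), p, and significance stars."""
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.beta / se
        df = max(self.n_clusters - 1, 1)
        p = 2 * stats.t.sf(np.abs(t), df)
        stars = ["***" if pi < 0.001 else "**" if pi < 0.01 else "*" if pi < 0.05 else ""
                 for pi in p]
        return pd.DataFrame(
            {"coef": self.beta, "se": se, "t": t, "p": p, "stars": stars},
            index=list(self.spec.terms),
        )

    @classmethod
    def from_coefficients(
        cls, spec: ModelSpec, beta, se=None, vcov=None
    ) -> "FittedDamageModel":
        """Wrap externally supplied coefficients (e.g. the published tables).

        Printed tables report per-coefficient SEs but not their covariances,
        so ``se`` alone cannot support prediction intervals; pass a full
        ``vcov`` for that.
        """
        beta = np.asarray(beta, float)
        if len(beta) != spec.n_terms:
            raise FitError("beta length must match the number of terms")
        if vcov is not None:
            vcov = np.asarray(vcov, float)
        fit = cls(spec=spec, beta=beta, vcov=vcov, n_obs=0, n_clusters=0)
        if se is not None and vcov is None:
            fit.vcov = None
            fit._se_only = np.asarray(se, float)  # informational only
        return fit


def reference_heat_fit() -> FittedDamageModel:
    """Published heat Model 4 coefficients, ready for point projection."""
    return FittedDamageModel.from_coefficients(
        ModelSpec("heat", MODEL_TERMS[4]), REFERENCE_HEAT_BETA, se=REFERENCE_HEAT_SE
    )


def reference_cold_fit() -> FittedDamageModel:
    """Published cold Model 3 coefficients, ready for point projection."""
    return FittedDamageModel.from_coefficients(
        ModelSpec("cold", MODEL_TERMS[3]), REFERENCE_COLD_BETA, se=REFERENCE_COLD_SE
    )


def fit_statistics(fit: FittedDamageModel, y: np.ndarray) -> tuple[float, float, float]:
    """In-sample (adj_r2, F, rmse) for a fitted model.

    rmse = sqrt(SSR/(n-k)).  R^2 uses the uncentered total sum of squares
    Sum(y^2) — the standard convention for regression through the origin —
    with adjustment 1 - (1-R2)*n/(n-k); the centered variant is stored on the
    fit as ``adj_r2_centered``.  F is the cluster-robust Wald statistic of
    all coefficients jointly zero, on (k, G-1) df.
    """
    y = np.asarray(y, float)
    r = fit.residuals
    n, k = fit.n_obs, len(fit.beta)
    if n <= k:
        raise FitError(f"need n > k for fit statistics (n={n}, k={k})")
    ssr = float(r @ r)
    rmse = np.sqrt(ssr / (n - k))
    tss_unc = float(y @ y)
    r2_unc = 1.0 - ssr / tss_unc if tss_unc > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2_unc) * n / (n - k)
    tss_c = float(((y - y.mean()) ** 2).sum())
    r2_c = 1.0 - ssr / tss_c if tss_c > 0 else np.nan
    fit.adj_r2_centered = 1.0 - (1.0 - r2_c) * n / (n - k)
    if fit.vcov is not None:
        try:
            w = float(fit.beta @ np.linalg.solve(fit.vcov, fit.beta))
        except np.linalg.LinAlgError:
            w = float(fit.beta @ np.linalg.pinv(fit.vcov) @ fit.beta)
        F = w / k if np.isfinite(w) else np.inf
        if not np.isfinite(w) or w < 0:
            F = np.inf
    else:
        F = np.nan
    fit.adj_r2, fit.F, fit.rmse = adj_r2, F, rmse
    return adj_r2, F, rmse


def fit_damage_model(
    X: np.ndarray,
    y: np.ndarray,
    cluster_ids,
    spec: ModelSpec | None = None,
    small_sample: str = "stata",
) -> FittedDamageModel:
    """No-intercept least squares with country-clustered sandwich covariance."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    cluster_ids = np.asarray(cluster_ids)
    if X.ndim == 1:
        X = X[:, None]
    terms = spec.terms if spec is not None else tuple(f"x{i}" for i in range(X.shape[1]))
    _check_rank(X, terms)
    groups = pd.unique(cluster_ids)
    if len(groups) < 2:
        raise FitError("need at least 2 clusters for cluster-robust inference")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ beta
    vcov = cluster_robust_vcov(X, residuals, cluster_ids, small_sample)
    if spec is None:
        # generic fit (oracles, raw arrays): placeholder spec of matching width
        spec = ModelSpec("heat", tuple(TERMS[: X.shape[1]]))
    fit = FittedDamageModel(
        spec=spec,
        beta=beta,
        vcov=vcov,
        n_obs=len(y),
        n_clusters=len(groups),
        residuals=residuals,
        X=X,
        y=y,
        cluster_ids=cluster_ids,
    )
    if len(y) > X.shape[1]:
        fit_statistics(fit, y)
    return fit


def fit_from_observations(
    observations: pd.DataFrame,
    country_records: pd.DataFrame,
    spec: ModelSpec,
    small_sample: str = "stata",
) -> FittedDamageModel:
    """Build the design from tables and fit in one step."""
    X = build_design(observations, country_records, spec)
    ycol = "y_hot" if spec.outcome == "heat" else "y_cold"
    return fit_damage_model(
        X,
        observations[ycol].to_numpy(float),
        observations["country"].to_numpy(),
        spec=spec,
        small_sample=small_sample,
    )


def crossvalidate(
    observations: pd.DataFrame,
    country_records: pd.DataFrame,
    spec: ModelSpec,
    unit: str = "country",
    small_sample: str = "stata",
) -> tuple[float, float, float]:
    """Leave-one-out cross-validation: (cv_rmse, cv_mae, pseudo_r2).

    unit="country" leaves out one country's 8 scenario-period rows at a time
    (matching the clustering and the extrapolate-to-new-countries goal);
    unit="observation" leaves out single rows.  pseudo_r2 = 1 - SSE_cv/TSS
    with the centered total sum of squares.
    """
    if unit not in ("country", "observation"):
        raise FitError(f"unit must be 'country' or 'observation', got {unit!r}")
    obs = observations.reset_index(drop=True)
    X = build_design(obs, country_records, spec)
    ycol = "y_hot" if spec.outcome == "heat" else "y_cold"
    y = obs[ycol].to_numpy(float)
    clusters = obs["country"].to_numpy()
    if unit == "country":
        folds = [np.flatnonzero(clusters == c) for c in pd.unique(clusters)]
    else:
        folds = [np.array([i]) for i in range(len(obs))]
    if len(folds) < 3:
        raise FitError(f"need >= 3 folds, got {len(folds)}")
    pred = np.empty_like(y)
    for fold_no, idx in enumerate(folds):
        keep = np.setdiff1d(np.arange(len(y)), idx)
        try:
            _check_rank(X[keep], spec.terms)
        except FitError as e:
            raise FitError(f"fold {fold_no} ({clusters[idx[0]]}): {e}") from e
        b, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        pred[idx] = X[idx] @ b
    err = y - pred
    cv_rmse = float(np.sqrt(np.mean(err**2)))
    cv_mae = float(np.mean(np.abs(err)))
    tss = float(((y - y.mean()) ** 2).sum())
    pseudo_r2 = 1.0 - float(err @ err) / tss if tss > 0 else np.nan
    return cv_rmse, cv_mae, pseudo_r2


def select_model(
    observations: pd.DataFrame,
    country_records: pd.DataFrame,
    outcome: str,
    specs: list[ModelSpec] | None = None,
    unit: str = "country",
    small_sample: str = "stata",
) -> pd.DataFrame:
    """Fit and cross-validate candidate specifications; rank by LOOCV RMSE.

    Returns the validation table (one row per candidate, ranked ascending by
    cv_rmse, ties broken by cv_mae then by fewer terms).  The fitted models
    are attached as ``result.attrs["fits"]``; the top-ranked fit is
    ``result.attrs["best"]``.
    """
    if specs is None:
        specs = candidate_specs(outcome)
    if len(specs) < 2:
        raise FitError("need at least 2 candidate specs to select among")
    rows, fits = [], []
    for i, spec in enumerate(specs):
        fit = fit_from_observations(observations, country_records, spec, small_sample)
        cv_rmse, cv_mae, pseudo = crossvalidate(
            observations, country_records, spec, unit, small_sample
        )
        fit.cv_rmse, fit.cv_mae, fit.cv_pseudo_r2 = cv_rmse, cv_mae, pseudo
        fits.append(fit)
        rows.append(
            {
                "model": i + 1,
                "terms": "+".join(spec.terms),
                "n_terms": spec.n_terms,
                "n_obs": fit.n_obs,
                "adj_r2": fit.adj_r2,
                "adj_r2_centered": fit.adj_r2_centered,
                "F": fit.F,
                "rmse": fit.rmse,
                "cv_rmse": cv_rmse,
                "cv_mae": cv_mae,
                "cv_pseudo_r2": pseudo,
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    order = table.sort_values(["cv_rmse", "cv_mae", "n_terms"], kind="stable").index
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order)
    table = table.sort_values("rank")
    table.attrs["fits"] = {m: fits[m - 1] for m in table.index}
    table.attrs["best"] = fits[table.index[0] - 1]
    return table
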