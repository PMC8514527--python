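# Methods

## Model and estimation

The package estimates two country-level damage functions — percent change
in heat-related and in cold-related mortality — from a response table of
country × scenario × period projections. Both are linear-in-parameters
regressions **through the origin**: zero warming must imply exactly zero
damage, so no specification ever includes a constant, and every fitted or
reference model returns identically 0 (point and interval) at dT = 0.

Candidate specifications are nested: (1) `T`; (2) `T, T²`;
(3) `+ T×ExtremeMonthTemp`; (4) `+ T×ExtremeMonthTemp×log GDPpc`, where the
extreme month is the hottest (heat) or coldest (cold) population-weighted
monthly mean, and income enters in natural logs of PPP dollars. Heat and
cold are fit as two separate regressions; no joint stacking, so the
cross-covariance of the two coefficient vectors is unidentified (see
Uncertainty below).

Coefficients solve ordinary least squares (numpy `lstsq`; verified in tests
against the explicit normal-equations solution on every tested instance).
The coefficient covariance is the cluster-robust sandwich with clusters =
countries, since one country's eight scenario-period rows share the same
underlying epidemiological response function. The small-sample factor is
configurable:

* `stata` (default): [G/(G−1)]·[(n−1)/(n−k)] — the convention of the
  reference validation tables, and identical to the statsmodels default
  (which tests use as an independent cross-check);
* `cr1`: G/(G−1); `none`: the plain sandwich.

With singleton clusters the default reduces exactly to HC1 (asserted in
tests). Coefficient significance uses t on G−1 degrees of freedom, starred
at p < 0.05 / 0.01 / 0.001.

### Fit statistics and the no-constant R² convention

RMSE = √(SSR/(n−k)). For regressions without a constant, R² computed
against the centered total sum of squares is not bounded or comparable
across conventions, so the reported `adj_r2` uses the **uncentered** total
Σy² with adjustment 1−(1−R²)·n/(n−k); the centered variant is also stored
(`adj_r2_centered`) because published tables do not always state their
convention. The F statistic is the cluster-robust Wald test of all
coefficients jointly zero on (k, G−1) df; it is +∞ for an exact fit.

### Cross-validation and model selection

Model choice is by leave-one-out cross-validation. "One" is ambiguous in a
clustered panel, so both fold units are implemented:

* `country` (default): leave out all of one country's rows — consistent
  with the clustering and with the purpose of the fit, extrapolation to
  countries outside the estimation sample;
* `observation`: leave out single rows.

CV statistics are RMSE and MAE over all held-out predictions, plus a
pseudo-R² = 1 − SSE_cv/Σ(y−ȳ)² (centered denominator, so it can be
negative for models worse than the grand mean). Candidates are ranked by
cv_rmse ascending; ties break by cv_mae, then by fewer terms (parsimony).
The country-fold LOOCV is tested against a brute-force refit loop.

## Projection, adaptation and uncertainty

A country projection evaluates the fitted (or shipped reference)
coefficient vectors at the country's design row. With income-based
adaptation the heat model's log-income is taken at the projection period's
midpoint year (defaults: 2055 for `mid`, 2090 for `end`), linearly
interpolated along the country's income path; the cold model has no income
term and is unchanged. `y_net = y_hot + y_cold` holds exactly by
construction.

Intervals are delta-method: a projection is linear in the coefficients, so
Var(x′β̂) = x′Vx exactly, with V the clustered covariance. Quantiles are
normal (`z`, default) or t on G−1 df via configuration — the choice of
construction is a package design decision, made once. Two deliberate
simplifications, both documented limitations:

* Var(net) = Var(hot) + Var(cold): the two separately fitted coefficient
  vectors are treated as independent because their cross-covariance is
  unidentified without a joint fit.
* dT is treated as fixed: climate-model ensemble spread is not propagated.

Countries lacking warming data, covariates, or (under adaptation) income
produce explicit missing rows with a reason, never silent zeros.

## Climatology

Country covariates come from a gridded 12-month climatology, gridded
population and a country mask (long-format CSV, or an in-memory xarray
Dataset). Monthly country values are population-weighted means over the
country's populated cells; cells are assigned wholly by the mask (no areal
splitting); a country with zero total population is an error. The order of
operations is fixed — **weight first, then pick the extreme month** of the
weighted cycle — because the covariate is a single scalar property of the
country's aggregate climate. The alternative (extremize each cell, then
average) differs in general; a constructed counterexample in the tests
documents the choice. Ties in the extreme month break toward the earliest
calendar month; months are 1-based (January = 1); temperatures are °C.
Multi-year series are assumed pre-averaged per calendar month before entry.

## Aggregation

Global rate changes are weighted means of country projections. Default
weights are expected baseline deaths (mortality_rate × population), the
natural weights for a *rate* change; population weights are available as a
sensitivity (the choice is a package decision — upstream sources rarely
state theirs). The global CI uses the weighted-sum design vector
x_glob = Σ w_c x_c against each covariance, which correctly carries the
perfect cross-country correlation induced by shared coefficients; averaging
per-country variances would shrink the interval spuriously (a test pins
this: aggregating identical countries leaves the interval width unchanged).

Excess deaths = (percent change / 100) × projected counterfactual deaths,
either globally or summed per country.

The warming-response curve needs country warming at arbitrary global-mean
warming levels; pattern scaling supplies it. Each country's ratio r_c is
the no-intercept least-squares slope of its dT on global dT across the
available discrete fields (single-point countries get the one-point ratio
with a warning). The curve grid defaults to 0–5 °C in 0.1 °C steps above
the 2001–2020 baseline, with a configurable preindustrial offset
(default 0.7 °C) reported alongside.

## Synthetic worlds

The generator emulates every pipeline input with known ground truth:

| quantity | law | default |
|---|---|---|
| countries | — | 23 (the reference study size) |
| hottest-month temp | uniform | 15–35 °C |
| coldest-month temp | uniform, jointly redrawn until < hottest | −25–20 °C |
| per-capita GDP PPP | log-uniform | \$1,000–\$60,000 |
| population | log-uniform | 1e6–3e8 |
| baseline mortality rate | uniform | 0.005–0.012 /person·yr |
| true heat coefficients | fixed | reference 4-term estimates |
| true cold coefficients | fixed | reference 3-term estimates |
| warming ratio r_c | lognormal, E[r]=1 | log-sd 0.15 |
| global dT (°C vs 2001–2020) | fixed table | mid 0.6/0.9/1.0/1.6; end 0.7/1.5/2.1/3.6 for RCP 2.6/4.5/6.0/8.5 |
| response noise | country effect + i.i.d. obs noise, both normal | total SD 2.25% (heat), 0.45% (cold), split 50/50 in variance |

The total noise SDs match the published in-sample RMSEs of the two
preferred specifications, so synthetic validation statistics land on the
same scale as the printed ones. Upstream sources state only that errors
are clustered by country, not a noise law; the normal random-effect
decomposition is an assumption chosen for tractable coverage analysis (it
makes the true intraclass correlation 0.5 under the default split). The
global dT table is chosen so end-of-century RCP 4.5 / RCP 8.5 sit at
2.2 / 4.3 °C above preindustrial with the default 0.7 °C offset.

Toy rasters are built backwards from the country record: a sinusoidal
annual cycle (January minimum = coldest covariate, July maximum = hottest)
plus per-cell perturbations whose population-weighted mean is exactly zero,
so the climatology module recovers the record to rounding error. Income
paths are single compound-growth trajectories per country.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: spatial autocorrelation of climate
fields; southern-hemisphere/equatorial seasonality (all toy cycles peak in
July); non-normal or heteroskedastic response noise; correlated covariates
(real hot countries are disproportionately poor; synthetic climate and
income are independent); scenario families beyond one growth path; and any
systematic misspecification of the damage-function form itself — in the
synthetic world the fitted specification family contains the truth.

## Verified statistical properties

At the study scale (23 countries × 8 scenario-periods, reference
coefficients as truth, matched noise), measured by the test suite and the
acceptance script:

* coefficient estimates unbiased (within 4 Monte-Carlo SEs over 500
  replicates);
* 95% cluster-robust CIs cover each true coefficient in 90–98% of
  replicates — slight undercoverage relative to nominal is expected with
  23 clusters and is the documented finite-cluster cost;
* the generating 4-term heat specification wins LOOCV selection in ≥80%
  of 200 replicates (empirically ~100%).

Problem sizes in tests (5–23 countries, 200–500 replicates) were chosen as
the smallest that make these Monte-Carlo bands tight enough to be
meaningful.

## Known limitations and edge cases

* The reference heat table's quadratic coefficient prints negative while
  the surrounding narrative describes a worsening (positive) curvature;
  the printed value (−0.0629) is treated as authoritative and shipped.
* The cold damage function with the reference coefficients is negative
  (beneficial) for dT ∈ (0, 5] across coldest-month means in [−30, 25] °C
  — but **not** beyond ~5.4 °C of country warming for the coldest
  countries, where the quadratic term dominates; the grid-checked property
  and the default curve grid stop at 5 °C.
* Reference fits ship per-coefficient standard errors only (printed tables
  carry no covariances), so they support point projections but not
  intervals; fit on data to get intervals.
* Rank-deficient designs, single clusters, n ≤ k, nonpositive incomes,
  negative dT, zero-population countries and all-missing aggregations
  raise typed errors naming the offending column/country/fold.
* NetCDF file IO is not provided; gridded inputs travel as long-format CSV
  or in-memory xarray Datasets.
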