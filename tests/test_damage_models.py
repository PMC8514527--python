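"""Estimation machinery: design construction, no-intercept least squares,
cluster-robust covariance (vs. explicit formulas and statsmodels), fit
statistics, leave-one-out cross-validation (vs. a brute-force refit loop),
and specification selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempmort.models import (
    MODEL_TERMS,
    FitError,
    FittedDamageModel,
    ModelSpec,
    build_design,
    candidate_specs,
    cluster_robust_vcov,
    crossvalidate,
    fit_damage_model,
    fit_from_observations,
    fit_statistics,
    select_model,
)

from conftest import replicate_bundle


def one_row_obs(country, dT):
    return pd.DataFrame({"country": [country], "dT": [dT]})


def records(**kw):
    """Country covariate frame from keyword rows: records(AAA=(hot, cold, gdp))."""
    return pd.DataFrame(
        {
            "hottest_month_temp": {k: v[0] for k, v in kw.items()},
            "coldest_month_temp": {k: v[1] for k, v in kw.items()},
            "gdp_pc_ppp": {k: v[2] for k, v in kw.items()},
        }
    ).rename_axis("country")


class TestBuildDesign:
    def test_heat_model4_hand_products(self):
        recs = records(AAA=(30.0, -5.0, float(np.exp(9.0))))
        X = build_design(one_row_obs("AAA", 2.0), recs, ModelSpec("heat", MODEL_TERMS[4]))
        assert np.allclose(X, [[2.0, 4.0, 60.0, 540.0]])

    def test_cold_model3_hand_products(self):
        recs = records(AAA=(30.0, -5.0, float(np.exp(9.0))))
        X = build_design(one_row_obs("AAA", 2.0), recs, ModelSpec("cold", MODEL_TERMS[3]))
        assert np.allclose(X, [[2.0, 4.0, -10.0]])

    def test_zero_warming_zero_row(self):
        recs = records(AAA=(31.7, -8.2, 12345.0))
        for spec in candidate_specs("heat") + candidate_specs("cold"):
            X = build_design(one_row_obs("AAA", 0.0), recs, spec)
            assert np.all(X == 0.0)

    def test_missing_country_named(self):
        recs = records(AAA=(30.0, -5.0, 1000.0))
        with pytest.raises(FitError, match="BBB"):
            build_design(one_row_obs("BBB", 1.0), recs, ModelSpec("heat", MODEL_TERMS[1]))

    def test_terms_ordered_as_spec(self, study_bundle):
        _, world, _, resp = study_bundle
        spec = ModelSpec("heat", ("T2", "T"))
        X = build_design(resp, world, spec)
        assert np.allclose(X[:, 1] ** 2, X[:, 0])


class TestFitDamageModel:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(24, 3))
        beta = np.array([1.5, -2.0, 0.25])
        clusters = np.repeat(np.arange(6), 4)
        fit = fit_damage_model(X, X @ beta, clusters)
        assert np.allclose(fit.beta, beta)
        assert np.allclose(fit.vcov, 0.0, atol=1e-18)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_hand_normal_equation_single_column(self):
        # beta = sum(x*y)/sum(x^2) = 29/14
        fit = fit_damage_model(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 5.0, 6.0]), ["a", "b", "c"]
        )
        assert fit.beta[0] == pytest.approx(29 / 14)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 4))
    def test_matches_normal_equations_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, k))
        y = rng.normal(size=30)
        clusters = rng.integers(0, 5, size=30)
        fit = fit_damage_model(X, y, clusters)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, oracle)
        # residual orthogonality to every design column
        assert np.abs(X.T @ fit.residuals).max() < 1e-8 * np.linalg.norm(y)

    def test_singleton_clusters_equal_hc1_sandwich(self):
        # with every observation its own cluster, the stata-factor clustered
        # sandwich reduces to the HC1 heteroskedasticity-robust estimator
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=40) * (1 + X[:, 0] ** 2)
        fit = fit_damage_model(X, y, np.arange(40))
        hc1 = sm.OLS(y, X).fit(cov_type="HC1").cov_params()
        assert np.allclose(fit.vcov, hc1)

    def test_cluster_vcov_matches_statsmodels(self, study_bundle):
        sm = pytest.importorskip("statsmodels.api")
        _, world, _, resp = study_bundle
        spec = ModelSpec("heat", MODEL_TERMS[4])
        fit = fit_from_observations(resp, world, spec)
        X = build_design(resp, world, spec)
        res = sm.OLS(resp["y_hot"].to_numpy(), X).fit(
            cov_type="cluster", cov_kwds={"groups": resp["country"].to_numpy()}
        )
        assert np.allclose(fit.beta, res.params)
        assert np.allclose(fit.vcov, res.cov_params())

    def test_vcov_invariant_to_row_order(self, study_bundle):
        _, world, _, resp = study_bundle
        spec = ModelSpec("heat", MODEL_TERMS[3])
        fit = fit_from_observations(resp, world, spec)
        shuffled = resp.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_from_observations(shuffled, world, spec)
        assert np.allclose(fit.vcov, fit2.vcov)
        eigvals = np.linalg.eigvalsh(fit.vcov)
        assert eigvals.min() >= -1e-12 * max(eigvals.max(), 1.0)

    def test_small_sample_factors(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        u = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        clusters = np.repeat(np.arange(5), 4)
        v_none = cluster_robust_vcov(X, u, clusters, "none")
        v_cr1 = cluster_robust_vcov(X, u, clusters, "cr1")
        v_stata = cluster_robust_vcov(X, u, clusters, "stata")
        assert np.allclose(v_cr1, v_none * 5 / 4)
        assert np.allclose(v_stata, v_none * (5 / 4) * (19 / 18))

    def test_single_cluster_rejected(self):
        with pytest.raises(FitError, match="cluster"):
            fit_damage_model(np.ones((4, 1)), np.ones(4), ["a"] * 4)

    def test_rank_deficiency_names_columns(self, study_bundle):
        _, world, _, resp = study_bundle
        world = world.copy()
        world["gdp_pc_ppp"] = np.e  # log GDP = 1 -> TxMxG duplicates TxM
        with pytest.raises(FitError, match="TxM"):
            fit_from_observations(resp, world, ModelSpec("heat", MODEL_TERMS[4]))

    def test_more_columns_than_rows_rejected(self):
        with pytest.raises(FitError, match="rows"):
            fit_damage_model(np.ones((2, 3)), np.ones(2), ["a", "b"])


class TestFitStatistics:
    def test_perfect_fit(self):
        X = np.arange(1.0, 7.0)[:, None]
        fit = fit_damage_model(X, 3 * X[:, 0], list("abcdef"))
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_hand_arithmetic_three_points(self):
        fit = fit_damage_model(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 5.0, 6.0]), ["a", "b", "c"]
        )
        resid = np.array([1 - 29 / 14, 5 - 58 / 14, 6 - 87 / 14])
        assert np.allclose(fit.residuals, resid)
        assert fit.rmse == pytest.approx(np.sqrt(resid @ resid / 2))

    def test_rmse_scale_equivariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        clusters = np.repeat(np.arange(4), 3)
        assert fit_damage_model(X, 2 * y, clusters).rmse == pytest.approx(
            2 * fit_damage_model(X, y, clusters).rmse
        )

    def test_underdetermined_statistics_rejected(self):
        fit = fit_damage_model(np.eye(2), np.ones(2), ["a", "b"])
        with pytest.raises(FitError, match="n > k"):
            fit_statistics(fit, np.ones(2))


class TestCrossValidation:
    def test_noiseless_perfect_cv(self, noiseless_responses):
        world, _, resp = noiseless_responses
        rmse, mae, pseudo = crossvalidate(resp, world, ModelSpec("heat", MODEL_TERMS[4]))
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert mae == pytest.approx(0.0, abs=1e-9)
        assert pseudo == pytest.approx(1.0)

    @pytest.mark.parametrize("unit", ["country", "observation"])
    def test_matches_bruteforce_refit_oracle(self, tiny_world, tiny_responses, unit):
        spec = ModelSpec("heat", MODEL_TERMS[3])
        rmse, mae, pseudo = crossvalidate(tiny_responses, tiny_world, spec, unit=unit)
        X = build_design(tiny_responses, tiny_world, spec)
        y = tiny_responses["y_hot"].to_numpy()
        c = tiny_responses["country"].to_numpy()
        pred = np.empty_like(y)
        if unit == "country":
            folds = [np.flatnonzero(c == cc) for cc in pd.unique(c)]
        else:
            folds = [[i] for i in range(len(y))]
        for idx in folds:
            keep = np.setdiff1d(np.arange(len(y)), idx)
            b = np.linalg.solve(X[keep].T @ X[keep], X[keep].T @ y[keep])
            pred[idx] = X[idx] @ b
        err = y - pred
        assert rmse == pytest.approx(np.sqrt(np.mean(err**2)))
        assert mae == pytest.approx(np.mean(np.abs(err)))
        assert pseudo == pytest.approx(1 - err @ err / ((y - y.mean()) ** 2).sum())

    def test_fold_count_contract(self, tiny_world, tiny_responses, monkeypatch):
        # one refit per fold: country mode runs n_countries fits,
        # observation mode one per row
        spec = ModelSpec("heat", MODEL_TERMS[2])
        calls = []
        real_lstsq = np.linalg.lstsq

        def counting_lstsq(*args, **kwargs):
            calls.append(1)
            return real_lstsq(*args, **kwargs)

        monkeypatch.setattr(np.linalg, "lstsq", counting_lstsq)
        crossvalidate(tiny_responses, tiny_world, spec, unit="country")
        assert len(calls) == tiny_world.shape[0]
        calls.clear()
        crossvalidate(tiny_responses, tiny_world, spec, unit="observation")
        assert len(calls) == len(tiny_responses)

    def test_bad_unit_rejected(self, tiny_world, tiny_responses):
        with pytest.raises(FitError, match="unit"):
            crossvalidate(tiny_responses, tiny_world, ModelSpec("heat", ("T",)), unit="x")

    def test_cv_rmse_at_least_insample_on_average(self):
        gaps = []
        for rep in range(30):
            _, world, _, resp = replicate_bundle(5_000 + rep)
            spec = ModelSpec("heat", MODEL_TERMS[4])
            fit = fit_from_observations(resp, world, spec)
            cv_rmse, _, _ = crossvalidate(resp, world, spec)
            gaps.append(cv_rmse - fit.rmse)
        assert np.mean(gaps) > 0


class TestSelectModel:
    def test_truth_model4_ranks_first(self, study_bundle):
        _, world, _, resp = study_bundle
        table = select_model(resp, world, "heat")
        assert table.index[0] == 4
        assert (table["rank"].to_numpy() == np.arange(1, 5)).all()
        assert table["cv_rmse"].is_monotonic_increasing

    def test_truth_model1_near_first(self):
        # data generated from the linear-only model: the parsimonious truth
        # should win or lose only narrowly to an overfit superset
        places = []
        for rep in range(20):
            _, world, _, resp = replicate_bundle(
                20_000 + rep, beta_hot=(2.0, 0.0, 0.0, 0.0)
            )
            table = select_model(resp, world, "heat")
            places.append(int(table.loc[1, "rank"]))
        assert np.median(places) <= 2

    def test_duplicate_specs_identical_rows(self, study_bundle):
        _, world, _, resp = study_bundle
        spec = ModelSpec("heat", MODEL_TERMS[2])
        table = select_model(resp, world, "heat", specs=[spec, spec])
        a, b = table.iloc[0], table.iloc[1]
        pd.testing.assert_series_equal(
            a.drop("rank"), b.drop("rank"), check_names=False
        )

    def test_coefficient_table_stars(self, study_bundle):
        _, world, _, resp = study_bundle
        table = select_model(resp, world, "cold")
        coefs = table.attrs["best"].coef_table()
        assert set(coefs.columns) == {"coef", "se", "t", "p", "stars"}
        assert ((coefs["p"] < 0.05) == (coefs["stars"] != "")).all()
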