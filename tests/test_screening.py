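import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from urbanscan import synth
from urbanscan.geo_core import CountPanel, DataError
from urbanscan.screening import (
    exclude_zero_count_areas,
    exploratory_regression,
    fit_ols,
    pearson_screen,
    run_funnel,
    vif,
)


class TestPearsonScreen:
    def test_perfect_correlation_retained(self, rng):
        x = rng.normal(size=50)
        df = pearson_screen(pd.DataFrame({"x": x}), x)
        assert df.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert df.loc[0, "pass"]

    def test_five_point_toy_product_moment(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 4, 5, 4, 5])
        df = pearson_screen(pd.DataFrame({"x": x}), y)
        assert df.loc[0, "pearson_r"] == pytest.approx(6 / np.sqrt(60), abs=1e-10)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(8)
        rejected = 0
        reps = 500
        for _ in range(reps):
            y = rng.normal(size=30)
            x = rng.normal(size=30)  # independent of y: null is true
            df = pearson_screen(pd.DataFrame({"x": x}), y)
            if df.loc[0, "pass"]:
                rejected += 1
        assert 0.02 < rejected / reps < 0.08

    def test_zero_variance_column_excluded_without_crash(self, rng):
        df = pearson_screen(
            pd.DataFrame({"flat": np.ones(20), "ok": rng.normal(size=20)}),
            rng.normal(size=20),
        )
        assert not df.set_index("variable").loc["flat", "pass"]


class TestVIF:
    def test_orthogonal_columns_give_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        assert vif(X).to_numpy() == pytest.approx([1.0, 1.0])

    def test_duplicated_column_is_infinite(self, rng):
        x = rng.normal(size=30)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v).all()

    def test_matches_statsmodels_oracle(self, rng):
        z = rng.normal(size=(60, 3))
        X = pd.DataFrame(
            {"a": z[:, 0], "b": 0.8 * z[:, 0] + 0.6 * z[:, 1], "c": z[:, 2] + 0.3 * z[:, 0]}
        )
        ours = vif(X)
        for j, name in enumerate(X.columns):
            others = sm.add_constant(X.drop(columns=name))
            r2 = sm.OLS(X[name], others).fit().rsquared
            assert ours[name] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestExploratoryRegression:
    def test_near_duplicates_one_survives_collinearity_pass(self, rng):
        x = rng.normal(size=80)
        X = pd.DataFrame(
            {"a": x, "b": x + 0.001 * rng.normal(size=80), "c": rng.normal(size=80)}
        )
        y = x + rng.normal(size=80)
        _, dropped, best = exploratory_regression(X, y)
        assert len(dropped) == 1
        assert dropped[0] in ("a", "b")

    def test_ranking_matches_brute_force_enumeration(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = 0.8 * X["a"] + 0.4 * X["b"] + rng.normal(size=n)
        models, _, best = exploratory_regression(X, y, max_size=3)
        # oracle: statsmodels adjusted R^2 over all subsets on standardized data
        yz = (y - y.mean()) / y.std(ddof=0)
        Xz = (X - X.mean()) / X.std(ddof=0)
        oracle = {}
        for size in (1, 2, 3):
            for combo in itertools.combinations(["a", "b", "c"], size):
                fit = sm.OLS(yz, sm.add_constant(Xz[list(combo)])).fit()
                oracle[combo] = fit.rsquared_adj
        for _, row in models.iterrows():
            assert row["adj_r2"] == pytest.approx(oracle[row["variables"]], abs=1e-10)
        admissible = models[models.admissible]
        top_oracle = max(
            (k for k in oracle if tuple(k) in set(admissible["variables"])),
            key=lambda k: oracle[k],
        )
        assert tuple(best) == top_oracle

    def test_strong_predictor_recovered(self):
        rng = np.random.default_rng(77)
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 100
            X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
            y = 1.0 * X["a"] + rng.normal(size=n)
            _, _, best = exploratory_regression(X, y, max_size=3)
            if "a" in best:
                hits += 1
        assert hits >= 95


class TestFitOLS:
    def test_perfect_fit_standardized_slope_one(self):
        x = np.linspace(0, 1, 30)
        res = fit_ols(pd.DataFrame({"x": x}), 2 * x)
        assert res.coef[1] == pytest.approx(1.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = X @ np.array([0.5, -0.3, 0.0, 0.8]) + rng.normal(size=n)
        res = fit_ols(X, y, standardize=False, prune=False)
        Z = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        np.testing.assert_allclose(res.coef, beta, atol=1e-10)
        fit = sm.OLS(np.asarray(y), Z).fit()
        assert res.r2 == pytest.approx(fit.rsquared, abs=1e-10)
        assert res.adj_r2 == pytest.approx(fit.rsquared_adj, abs=1e-10)
        np.testing.assert_allclose(res.p, fit.pvalues, atol=1e-10)

    def test_known_coefficients_recovered_within_3_se(self):
        rng = np.random.default_rng(5)
        n = 140
        beta = np.array([0.6, -0.4, 0.3, 0.5])
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = X @ beta + rng.normal(size=n) * 0.5
        res = fit_ols(X, y, standardize=False, prune=False)
        for j in range(4):
            assert abs(res.coef[j + 1] - beta[j]) < 3 * res.se[j + 1]

    def test_pure_noise_usually_pruned_to_intercept(self):
        # with 4 independent noise columns at alpha=0.05 the chance that
        # none survives backward pruning is bounded near (1-0.05)^4 ~ 0.81
        rng = np.random.default_rng(9)
        empty = 0
        n_kept = 0
        reps = 50
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
            y = rng.normal(size=60)
            res = fit_ols(X, y)
            if len(res.names) == 0:
                empty += 1
            n_kept += len(res.names)
        assert empty >= int(0.6 * reps)
        assert n_kept / reps <= 0.75

    def test_singular_design_is_error(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(DataError, match="singular|collinear"):
            fit_ols(pd.DataFrame({"a": x, "b": x}), rng.normal(size=30),
                    standardize=False, prune=False)


class TestFunnel:
    def test_stage_assignment_is_a_partition(self):
        rng = np.random.default_rng(15)
        n = 140
        X = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"v{i}" for i in range(8)])
        X["v7"] = X["v0"] * 0.999 + 0.001 * rng.normal(size=n)  # collinear pair
        y = 0.8 * X["v0"] - 0.5 * X["v1"] + rng.normal(size=n)
        report, ols = run_funnel(X, y)
        stages = report.table["stage"]
        assert stages.notna().all()
        assert len(stages) == 8
        assert set(stages).issubset({"pearson", "collinearity", "subset-search", "ols", "retained"})

    def test_paper_shaped_funnel_recovers_actives(self):
        # 25 candidates, 4 truly active, spatially structured like the fixture
        hits = 0
        reps = 5
        for r in range(reps):
            areas = synth.make_lattice(synth.SimulationSpec(nx=12, ny=12, seed=50 + r))
            names = [f"v{i:02d}" for i in range(25)]
            synth.simulate_covariates(areas, names, range_m=3000.0, seed=60 + r)
            X = areas.covariates[names]
            rng = np.random.default_rng(70 + r)
            y = (
                0.5 * X["v00"] - 0.45 * X["v01"] + 0.4 * X["v02"] + 0.45 * X["v03"]
                + 0.5 * rng.normal(size=144)
            )
            report, _ = run_funnel(X, y, max_size=6)
            got = set(report.retained)
            if len(got & {"v00", "v01", "v02", "v03"}) >= 3:
                hits += 1
        assert hits >= int(0.8 * reps)


class TestZeroCountExclusion:
    def make(self, counts, lattice):
        n = counts.shape[0]
        return CountPanel(
            counts=counts,
            population=lattice.population[:n],
            years=np.arange(2012, 2012 + counts.shape[1]),
            area_id=lattice.area_id[:n],
        )

    def test_removes_and_logs_zero_areas(self, lattice_5x5):
        counts = np.ones((25, 2), dtype=int)
        counts[[3, 10, 17]] = 0
        panel = self.make(counts, lattice_5x5)
        areas2, panel2, removed = exclude_zero_count_areas(lattice_5x5, panel)
        assert areas2.n == 22
        assert len(removed) == 3
        assert set(removed) == {str(lattice_5x5.area_id[i]) for i in (3, 10, 17)}

    def test_identity_when_no_zero_areas(self, lattice_5x5):
        counts = np.ones((25, 2), dtype=int)
        panel = self.make(counts, lattice_5x5)
        areas2, panel2, removed = exclude_zero_count_areas(lattice_5x5, panel)
        assert areas2.n == 25 and removed == []

    def test_all_zero_is_error(self, lattice_5x5):
        panel = self.make(np.zeros((25, 2), dtype=int), lattice_5x5)
        with pytest.raises(DataError):
            exclude_zero_count_areas(lattice_5x5, panel)
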