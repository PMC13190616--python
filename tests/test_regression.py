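"""OLS, VIF pruning, LM diagnostics, and ML spatial models."""

import numpy as np
import pandas as pd
import pytest

import spatq
from spatq import (
    RegressionSpec,
    fit_ols,
    fit_sem,
    fit_slm,
    lm_diagnostics,
    residual_moran,
    vif_prune,
)
from spatq import synthetic as syn


def ols_normal_equations(y, X):
    return np.linalg.solve(X.T @ X, X.T @ y)


def make_table(rng, n, p, y=None):
    X = rng.normal(size=(n, p))
    if y is None:
        y = X @ rng.normal(size=p) + rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    df["y"] = y
    return df


class TestOls:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        fit = fit_ols(df, RegressionSpec("y", ("x",), standardize=False))
        assert fit.coefficients[1] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)

    def test_standardized_intercept_zero(self, rng):
        df = make_table(rng, 40, 3)
        fit = fit_ols(df, RegressionSpec("y", ("x0", "x1", "x2")))
        assert abs(fit.coefficients[0]) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            n, p = int(rng.integers(20, 60)), int(rng.integers(1, 5))
            df = make_table(rng, n, p)
            spec = RegressionSpec("y", tuple(f"x{j}" for j in range(p)),
                                  standardize=False)
            fit = fit_ols(df, spec)
            X = np.column_stack([np.ones(n), df[[f"x{j}" for j in range(p)]]])
            expect = ols_normal_equations(df["y"].to_numpy(), X)
            np.testing.assert_allclose(fit.coefficients, expect, rtol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        df = make_table(rng, 50, 3)
        fit = fit_ols(df, RegressionSpec("y", ("x0", "x1", "x2")))
        X = np.column_stack([np.ones(50),
                             ((df - df.mean()) / df.std(ddof=0))[["x0", "x1", "x2"]]])
        np.testing.assert_allclose(X.T @ fit.residuals, 0, atol=1e-8)

    def test_aic_identity(self, rng):
        df = make_table(rng, 50, 2)
        fit = fit_ols(df, RegressionSpec("y", ("x0", "x1")))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood)

    def test_rank_deficient_names_column(self, rng):
        df = make_table(rng, 30, 2)
        df["x2"] = df["x0"] * 2
        with pytest.raises(ValueError, match="x2|x0"):
            fit_ols(df, RegressionSpec("y", ("x0", "x1", "x2"),
                                       standardize=False))

    def test_null_slope_rarely_significant(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.normal(size=200),
                               "y": rng.normal(size=200)})
            fit = fit_ols(df, RegressionSpec("y", ("x",)))
            hits += fit.p_values[1] < 0.05
        assert hits <= 40 * 0.10  # >= 90% non-significant


class TestVif:
    def test_orthogonal_columns_vif_one(self):
        n = 64
        df = pd.DataFrame({
            "x0": np.tile([1.0, -1.0], n // 2),
            "x1": np.repeat([1.0, -1.0], n // 2),
            "y": np.zeros(n),
        })
        rep = vif_prune(df, RegressionSpec("y", ("x0", "x1")))
        assert all(v == pytest.approx(1.0) for v in rep.vif.values())
        assert rep.dropped == ()

    def test_near_duplicate_dropped(self, rng):
        x1 = rng.normal(size=100)
        df = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-3, 100),
                           "x3": rng.normal(size=100), "y": np.zeros(100)})
        rep = vif_prune(df, RegressionSpec("y", ("x1", "x2", "x3")))
        assert len(rep.dropped) == 1 and rep.dropped[0] in ("x1", "x2")
        assert max(rep.vif.values()) < 5

    def test_matches_definitional_oracle(self, rng):
        n = 80
        X = rng.normal(size=(n, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=n)
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        df["y"] = 0.0
        rep = vif_prune(df, RegressionSpec("y", ("a", "b", "c", "d")),
                        threshold=1e9)  # no dropping; report raw VIFs
        for j, name in enumerate(["a", "b", "c", "d"]):
            others = [c for c in ["a", "b", "c", "d"] if c != name]
            Z = np.column_stack([np.ones(n), df[others]])
            yj = df[name].to_numpy()
            b = np.linalg.solve(Z.T @ Z, Z.T @ yj)
            r2 = 1 - ((yj - Z @ b) ** 2).sum() / ((yj - yj.mean()) ** 2).sum()
            assert rep.vif[name] == pytest.approx(1 / (1 - r2), abs=1e-9)

    def test_collinear_block_pruned_in_study_fixture(self):
        ds = syn.simulate_study_like(seed=11)
        rep = vif_prune(ds.table,
                        RegressionSpec("life_expectancy", syn.STUDY_COVARIATES))
        assert len(rep.dropped) >= 1
        assert set(rep.dropped) <= set(ds.truth["collinear_block"])
        assert max(rep.vif.values()) < 5

    def test_requires_two_covariates(self, rng):
        df = make_table(rng, 20, 1)
        with pytest.raises(ValueError, match="2 covariates"):
            vif_prune(df, RegressionSpec("y", ("x0",)))


def sar_table(lattice, rho, seed, beta=(0.0, 1.0, 2.0), sigma=1.0):
    rng = np.random.default_rng(seed)
    X = syn.simulate_covariates(lattice, np.eye(2), delta=0.3,
                                seed=int(rng.integers(2**31)))
    y, _ = syn.simulate_sar_outcome(lattice, X.to_numpy(), beta=beta, rho=rho,
                                    sigma=sigma, seed=int(rng.integers(2**31)))
    df = pd.DataFrame({"y": y, "x1": X.iloc[:, 0], "x2": X.iloc[:, 1]})
    return df, RegressionSpec("y", ("x1", "x2"))


class TestLmDiagnostics:
    def test_statistics_nonnegative(self, lattice10):
        df, spec = sar_table(lattice10, rho=0.4, seed=0)
        fit = fit_ols(df, spec)
        d = lm_diagnostics(fit, lattice10.weights_std, df, spec)
        assert min(d.lm_lag, d.lm_error, d.robust_lm_lag, d.robust_lm_error) >= 0

    def test_recommends_slm_under_lag_truth(self, lattice10):
        recs = [
            lm_diagnostics(
                fit_ols(*sar_table(lattice10, rho=0.7, seed=s)),
                lattice10.weights_std, *sar_table(lattice10, rho=0.7, seed=s),
            ).recommendation
            for s in range(10)
        ]
        assert recs.count("SLM") >= 8

    def test_recommends_ols_without_spatial_structure(self, lattice10):
        recs = []
        for s in range(10):
            df, spec = sar_table(lattice10, rho=0.0, seed=100 + s)
            recs.append(lm_diagnostics(fit_ols(df, spec),
                                       lattice10.weights_std, df, spec
                                       ).recommendation)
        assert recs.count("OLS") >= 7

    def test_requires_ols_fit(self, lattice10):
        df, spec = sar_table(lattice10, rho=0.5, seed=1)
        slm = fit_slm(df, spec, lattice10.weights_std)
        with pytest.raises(ValueError, match="OLS"):
            lm_diagnostics(slm, lattice10.weights_std, df, spec)


class TestSlm:
    def test_nests_ols_at_rho_zero(self, lattice10):
        df, spec = sar_table(lattice10, rho=0.0, seed=2)
        ols = fit_ols(df, spec)
        slm = fit_slm(df, spec, lattice10.weights_std)
        assert abs(slm.spatial_param) < 0.25
        for b_s, b_o, se in zip(slm.coefficients[1:], ols.coefficients[1:],
                                ols.std_errors[1:]):
            assert abs(b_s - b_o) < 2 * se

    def test_loglik_dominates_rho_zero(self, lattice10):
        for s in range(3):
            df, spec = sar_table(lattice10, rho=0.5, seed=s)
            slm = fit_slm(df, spec, lattice10.weights_std)
            ols = fit_ols(df, spec)  # rho = 0 likelihood
            assert slm.log_likelihood >= ols.log_likelihood - 1e-8

    def test_optimum_is_local_max(self, lattice10):
        df, spec = sar_table(lattice10, rho=0.5, seed=3)
        slm = fit_slm(df, spec, lattice10.weights_std)
        ll = _slm_conc_ll(df, spec, lattice10.weights_std)
        for d in (-0.01, 0.01):
            assert ll(slm.spatial_param) >= ll(slm.spatial_param + d) - 1e-9

    def test_spatial_param_within_bounds(self, lattice10):
        df, spec = sar_table(lattice10, rho=0.8, seed=4)
        slm = fit_slm(df, spec, lattice10.weights_std)
        assert -1 < slm.spatial_param < 1

    def test_aic_favors_slm_on_lag_data(self, lattice10):
        wins = 0
        for s in range(10):
            df, spec = sar_table(lattice10, rho=0.6, seed=200 + s)
            wins += (fit_slm(df, spec, lattice10.weights_std).aic
                     < fit_ols(df, spec).aic)
        assert wins >= 8


def _slm_conc_ll(df, spec, w):
    from spatq.regression import _design, _w_eigenvalues
    y, X, _ = _design(df, spec)
    n = len(y)
    eig = _w_eigenvalues(w)
    Wy = w.matrix @ y

    def ll(rho):
        b = np.linalg.lstsq(X, y - rho * Wy, rcond=None)[0]
        e = y - rho * Wy - X @ b
        s2 = (e @ e) / n
        return -0.5 * n * (np.log(2 * np.pi * s2) + 1) + np.log(1 - rho * eig).sum()

    return ll


class TestSem:
    def test_nests_ols_at_lambda_zero(self, lattice10):
        rng = np.random.default_rng(5)
        X = syn.simulate_covariates(lattice10, np.eye(2), seed=6)
        y, _ = syn.simulate_sem_outcome(lattice10, X.to_numpy(),
                                        beta=[0, 1, 2], lam=0.0, seed=7)
        df = pd.DataFrame({"y": y, "x1": X.iloc[:, 0], "x2": X.iloc[:, 1]})
        spec = RegressionSpec("y", ("x1", "x2"))
        ols, sem = fit_ols(df, spec), fit_sem(df, spec, lattice10.weights_std)
        for b_s, b_o, se in zip(sem.coefficients[1:], ols.coefficients[1:],
                                ols.std_errors[1:]):
            assert abs(b_s - b_o) < 2 * se

    def test_whitening_filtered_residuals(self, lattice10):
        from spatq import global_moran
        ok = 0
        for s in range(5):
            X = syn.simulate_covariates(lattice10, np.eye(2), seed=10 + s)
            y, _ = syn.simulate_sem_outcome(lattice10, X.to_numpy(),
                                            beta=[0, 1, 2], lam=0.6,
                                            seed=50 + s)
            df = pd.DataFrame({"y": y, "x1": X.iloc[:, 0], "x2": X.iloc[:, 1]})
            sem = fit_sem(df, RegressionSpec("y", ("x1", "x2")),
                          lattice10.weights_std)
            B = np.eye(100) - sem.spatial_param * lattice10.weights_std.matrix
            filtered = B @ sem.residuals
            z = global_moran(filtered, lattice10.weights_std).z_score
            ok += abs(z) < 2
        assert ok >= 4


class TestResidualMoran:
    def test_ols_on_lag_data_leaves_autocorrelation(self, lattice10):
        hits = 0
        for s in range(10):
            df, spec = sar_table(lattice10, rho=0.7, seed=300 + s)
            hits += residual_moran(fit_ols(df, spec),
                                   lattice10.weights_std).p_value < 0.05
        assert hits >= 8

    def test_slm_whitens_residuals(self, lattice10):
        ok = 0
        for s in range(10):
            df, spec = sar_table(lattice10, rho=0.7, seed=300 + s)
            slm = fit_slm(df, spec, lattice10.weights_std)
            ok += residual_moran(slm, lattice10.weights_std).p_value >= 0.05
        assert ok >= 8

    def test_zero_residuals_error(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        fit = fit_ols(df, RegressionSpec("y", ("x",), standardize=False))
        from spatq import from_adjacency_pairs, row_standardize
        ids = list(range(10))
        w = row_standardize(from_adjacency_pairs(
            [(i, (i + 1) % 10) for i in range(10)], ids))
        with pytest.raises(ValueError, match="zero variance"):
            residual_moran(fit, w)
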