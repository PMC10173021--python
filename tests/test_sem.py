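"""Path-model ML fit: covariance algebra, oracles, robustness, fit indices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pathmed as pm
from pathmed import sem

from conftest import scaled_groups


class TestImpliedCovariance:
    def test_no_edges_block_diagonal(self):
        Phi = np.array([[2.0, 0.5], [0.5, 1.0]])
        Psi = np.array([1.0, 3.0])
        S = pm.implied_covariance(np.zeros((2, 2)), np.zeros((2, 2)) * 0, Psi, Phi)
        expect = np.zeros((4, 4))
        expect[:2, :2] = Phi
        expect[2:, 2:] = np.diag(Psi)
        assert np.allclose(S, expect)

    def test_three_node_chain_hand_traced(self):
        """X -> M -> Y with both coefficients 0.5 and unit residual
        variances: cov(X, Y) = 0.25 by path tracing."""
        B = np.array([[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0.0]])
        S = pm.implied_covariance(B, np.zeros((3, 0)), np.ones(3),
                                  np.zeros((0, 0)))
        assert abs(S[0, 2] - 0.25) < 1e-15
        assert abs(S[1, 1] - 1.25) < 1e-15     # var(M) = 0.25 + 1

    def test_matches_monte_carlo(self, rng):
        q, k, n = 2, 3, 400000
        Phi = np.array([[1.0, 0.3], [0.3, 2.0]])
        G = rng.normal(size=(k, q)) * 0.5
        B = np.tril(rng.normal(size=(k, k)) * 0.4, -1)
        Psi = np.array([0.5, 0.8, 1.2])
        Sig = pm.implied_covariance(B, G, Psi, Phi)
        x = rng.normal(size=(n, q)) @ np.linalg.cholesky(Phi).T
        y = (x @ G.T + rng.normal(size=(n, k)) * np.sqrt(Psi)) \
            @ np.linalg.inv(np.eye(k) - B).T
        Shat = np.cov(np.hstack([x, y]), rowvar=False)
        # entrywise 3-SE bound for a sample covariance
        d = np.diag(Sig)
        se = np.sqrt((np.outer(d, d) + Sig ** 2) / n)
        assert (np.abs(Shat - Sig) < 3.5 * se).all()

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            pm.implied_covariance(np.zeros((2, 2)), np.zeros((3, 1)),
                                  np.ones(2), np.eye(1))


def _simulated_frame(rng, n=20000):
    """Small linear recursive system with two exogenous covariates."""
    x = rng.normal(size=(n, 2))
    m1 = 0.4 * x[:, 0] - 0.2 * x[:, 1] + rng.normal(size=n)
    m2 = 0.5 * m1 + 0.1 * x[:, 0] + rng.normal(size=n)
    y = 0.3 * m1 - 0.4 * m2 + 0.2 * x[:, 1] + rng.normal(size=n)
    return pd.DataFrame({"age": x[:, 0], "sex": x[:, 1],
                         "m1": m1, "m2": m2, "y": y})


@pytest.fixture()
def chain_dag():
    return pm.DagSpec(nodes=["m1", "m2", "y"],
                      edges=[("m1", "m2"), ("m1", "y"), ("m2", "y")],
                      covariates=["age", "sex"])


class TestFitMl:
    def test_saturated_model_equals_per_equation_ols(self, rng, chain_dag):
        """Saturated recursive model: F = T = 0 and every coefficient equals
        its per-equation OLS value to 1e-6."""
        import statsmodels.api as smapi
        df = _simulated_frame(rng)
        fit = pm.fit_ml(df, chain_dag)
        assert fit.df == 0
        assert abs(fit.F_ML) < 1e-12 and abs(fit.T) < 1e-9
        assert fit.converged
        for child, preds in [("m1", ["age", "sex"]),
                             ("m2", ["age", "sex", "m1"]),
                             ("y", ["age", "sex", "m1", "m2"])]:
            ols = smapi.OLS(df[child], smapi.add_constant(df[preds])).fit()
            for p in preds:
                assert abs(fit.coefficient(child, p) - ols.params[p]) < 1e-6

    def test_quasi_newton_agrees_with_closed_form(self, rng, chain_dag):
        df = _simulated_frame(rng, 5000)
        a = pm.fit_ml(df, chain_dag, refine=True)
        b = pm.fit_ml(df, chain_dag, refine=False)
        assert np.abs(a.B - b.B).max() < 1e-8
        assert np.abs(a.G - b.G).max() < 1e-8

    def test_scipy_optimizer_from_perturbed_start_finds_same_optimum(
            self, rng, chain_dag):
        """Generic minimization of F_ML started away from the solution lands
        on the closed-form estimates (independent optimization route)."""
        from scipy.optimize import minimize
        df = _simulated_frame(rng, 4000)
        fit = pm.fit_ml(df, chain_dag, refine=False)
        S = fit.S
        logdet_S = np.linalg.slogdet(S)[1]
        Phi = fit.Phi
        idx = fit.param_index
        theta_hat = sem._pack(fit.B, fit.G, fit.Psi, chain_dag, idx)
        theta0 = theta_hat + rng.normal(size=theta_hat.size) * 0.2
        theta0[[idx[("psi", n, "")] for n in chain_dag.nodes]] = 1.0
        res = minimize(lambda t: sem._gradient(t, S, Phi, chain_dag, idx,
                                               logdet_S),
                       theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "gtol": 1e-10})
        assert np.abs(res.x - theta_hat).max() < 1e-4

    def test_parameter_recovery_single_seed(self, small_config, small_table,
                                            default_dag):
        fit = pm.fit_ml(pm.binarize_sep(small_table, "MA_vs_rest"), default_dag,
                        compute_indices=False)
        Btrue = pm.true_b_matrix(small_config, default_dag)
        nodes = default_dag.nodes
        for _kind, child, parent in fit.free_b_params():
            est = fit.coefficient(child, parent)
            truth = Btrue[nodes.index(child), nodes.index(parent)]
            assert abs(est - truth) < 3.5 * fit.se(child, parent), (child, parent)

    def test_omitted_edge_statistic_grows_with_n(self, rng):
        """Dropping a real edge makes T grow roughly linearly in N."""
        wrong = pm.DagSpec(nodes=["m1", "m2", "y"],
                           edges=[("m1", "m2"), ("m2", "y")],
                           covariates=["age", "sex"])
        df = _simulated_frame(rng, 80000)
        t_small = pm.fit_ml(df.iloc[:20000], wrong, robust=False).T
        t_large = pm.fit_ml(df, wrong, robust=False).T
        assert t_large > 50          # real misfit detected
        assert 2.0 < t_large / t_small < 8.0

    def test_row_shuffle_invariance(self, rng, chain_dag):
        df = _simulated_frame(rng, 3000)
        a = pm.fit_ml(df, chain_dag)
        b = pm.fit_ml(df.sample(frac=1.0, random_state=1), chain_dag)
        assert np.abs(a.B - b.B).max() < 1e-12
        assert abs(a.T - b.T) < 1e-9

    def test_rescaling_transforms_coefficients(self, rng, chain_dag):
        """Multiplying a variable by c rescales its coefficients by
        c_child / c_parent, leaving T unchanged."""
        df = _simulated_frame(rng, 3000)
        a = pm.fit_ml(df, chain_dag, robust=False)
        df2 = df.copy()
        df2["m1"] = df2["m1"] * 10.0
        b = pm.fit_ml(df2, chain_dag, robust=False)
        assert abs(b.coefficient("m2", "m1") -
                   a.coefficient("m2", "m1") / 10.0) < 1e-10
        assert abs(b.coefficient("m1", "age") -
                   a.coefficient("m1", "age") * 10.0) < 1e-9
        assert abs(a.T - b.T) < 1e-8

    def test_non_pd_covariance_raises(self, chain_dag):
        S = np.zeros((5, 5))
        with pytest.raises(ValueError, match="positive definite"):
            pm.fit_ml(None, chain_dag, S=S, N=100)

    def test_robust_and_naive_se_close_for_gaussian_errors(self, rng, chain_dag):
        """With Gaussian residuals the sandwich and information SEs agree."""
        df = _simulated_frame(rng, 40000)
        fit = pm.fit_ml(df, chain_dag)
        i = fit.param_index[("B", "y", "m2")]
        assert abs(np.sqrt(fit.vcov[i, i]) / np.sqrt(fit.vcov_naive[i, i]) - 1) \
            < 0.1
        # and the SB scaling is near 1
        wrong = pm.DagSpec(nodes=["m1", "m2", "y"],
                           edges=[("m1", "m2"), ("m2", "y")],
                           covariates=["age", "sex"])
        f2 = pm.fit_ml(df, wrong)
        assert 0.8 < f2.scaling < 1.2


class TestFitIndices:
    def test_perfect_fit_limits(self, rng, chain_dag):
        df = _simulated_frame(rng, 2000)
        fit = pm.fit_ml(df, chain_dag)   # saturated: Sigma == S
        idx = fit.indices
        assert idx.rmsea == 0.0
        assert idx.srmr < 1e-8
        assert abs(idx.gfi - 1.0) < 1e-12
        assert idx.cfi == 1.0

    def test_rmsea_closed_form(self):
        assert abs(sem.rmsea(100.0, 50, 1001) - np.sqrt(50 / 50000)) < 1e-15

    def test_cfi_closed_form(self):
        assert abs(sem.cfi(100.0, 50, 1000.0, 60) - (1 - 50 / 940)) < 1e-15
        assert sem.cfi(40.0, 50, 1000.0, 60) == 1.0      # T < df

    def test_robust_indices_reduce_to_plain_when_scaling_unity(
            self, rng, chain_dag):
        df = _simulated_frame(rng, 3000)
        fit = pm.fit_ml(df, chain_dag, robust=False)
        assert fit.scaling == 1.0
        plain = sem.fit_indices(fit, robust=False)
        rob = sem.fit_indices(fit, robust=True)
        assert plain == rob

    def test_baseline_statistic_independence_model(self, rng, chain_dag):
        df = _simulated_frame(rng, 3000)
        fit = pm.fit_ml(df, chain_dag)
        T_b, df_b = sem.baseline_statistic(fit.S, fit.N)
        p = fit.S.shape[0]
        assert df_b == p * (p - 1) // 2
        # direct recomputation of the independence discrepancy
        F_b = np.sum(np.log(np.diag(fit.S))) - np.linalg.slogdet(fit.S)[1]
        assert abs(T_b - (fit.N - 1) * F_b) < 1e-9
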