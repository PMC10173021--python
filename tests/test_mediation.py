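"""Pathway enumeration, product-of-coefficients effects, proportions, CIs."""

from __future__ import annotations

import numpy as np
import pytest

import pathmed as pm
from pathmed.mediation import (Pathway, _select_paths, path_effects_from_b,
                               pathway_effect)
from pathmed.sem import PathModelFit, _parameterize

from conftest import scaled_groups


def dfs_all_paths(edges, source, target):
    """Independent brute-force DFS path enumeration."""
    out = []

    def walk(node, trail):
        if node == target:
            out.append(trail)
            return
        for u, v in edges:
            if u == node and v not in trail:
                walk(v, trail + [v])

    walk(source, [source])
    return sorted(out)


def manual_fit(dag, B, vcov=None):
    """Minimal PathModelFit carrying just coefficients and a vcov."""
    index = _parameterize(dag)
    k = len(dag.nodes)
    q = len(dag.covariates)
    V = np.zeros((len(index), len(index))) if vcov is None else vcov
    return PathModelFit(
        dag=dag, var_names=dag.covariates + dag.nodes, B=B,
        G=np.zeros((k, q)), Psi=np.ones(k), Phi=np.eye(q),
        S=np.eye(q + k), Sigma=np.eye(q + k), N=1000, F_ML=0.0, T=0.0,
        df=0, scaling=1.0, param_index=index, vcov=V, vcov_naive=V,
        converged=True)


def random_b(dag, rng, lo=-0.5, hi=0.5):
    B = np.zeros((len(dag.nodes),) * 2)
    idx = {n: i for i, n in enumerate(dag.nodes)}
    for u, v in dag.edges:
        B[idx[v], idx[u]] = rng.uniform(lo, hi)
    return B


class TestEnumeration:
    def test_chain_plus_direct_two_paths(self):
        dag = pm.DagSpec(nodes=["x", "m", "y"],
                         edges=[("x", "m"), ("m", "y"), ("x", "y")],
                         covariates=[])
        paths = pm.enumerate_paths(dag)
        assert [p.nodes for p in paths] == [["x", "m", "y"], ["x", "y"]]

    @pytest.mark.parametrize("dag_factory", [pm.default_dag, pm.admitted_dag])
    def test_matches_brute_force_dfs(self, dag_factory):
        dag = dag_factory()
        ours = [p.nodes for p in pm.enumerate_paths(dag)]
        brute = dfs_all_paths(dag.edges, dag.exposure, dag.outcome)
        assert ours == brute

    def test_no_route_empty(self):
        dag = pm.DagSpec(nodes=["x", "m", "y"], edges=[("x", "m")],
                         covariates=[])
        assert pm.enumerate_paths(dag) == []

    def test_unknown_node_raises(self, default_dag):
        with pytest.raises(ValueError, match="not a node"):
            pm.enumerate_paths(default_dag, "nope", None)


class TestPathwayEffects:
    def test_two_edge_product(self):
        dag = pm.DagSpec(nodes=["x", "m", "y"],
                         edges=[("x", "m"), ("m", "y"), ("x", "y")],
                         covariates=["age"])
        B = np.array([[0, 0, 0], [0.5, 0, 0], [0.1, 0.4, 0]])
        fit = manual_fit(dag, B)
        eff = pathway_effect(fit, "m")
        assert abs(eff.effect - 0.20) < 1e-15
        td = pm.total_and_direct(fit)
        assert abs(td["total"] - 0.30) < 1e-15
        assert abs(td["direct"] - 0.10) < 1e-15

    @pytest.mark.parametrize("dag_factory,seed",
                             [(pm.default_dag, 0), (pm.default_dag, 1),
                              (pm.admitted_dag, 2), (pm.admitted_dag, 3)])
    def test_decomposition_identity(self, dag_factory, seed):
        """direct + sum of all indirect path products = reduced-form total,
        to 1e-10, for random coefficient draws."""
        dag = dag_factory()
        rng = np.random.default_rng(seed)
        fit = manual_fit(dag, random_b(dag, rng))
        td = pm.total_and_direct(fit)    # raises internally if identity fails
        indirect = sum(np.prod([fit.coefficient(v, u) for u, v in p.edges()])
                       for p in pm.enumerate_paths(dag) if len(p.nodes) > 2)
        assert abs(td["total"] - td["direct"] - indirect) < 1e-12

    def test_exclusion_selector_matches_brute_force_filter(self, default_dag):
        rng = np.random.default_rng(7)
        fit = manual_fit(default_dag, random_b(default_dag, rng))
        eff = pathway_effect(fit, "bystander_cpr", ("witnessed",))
        paths = dfs_all_paths(default_dag.edges, "sep_binary", "surv_discharge")
        expect = 0.0
        for p in paths:
            if "bystander_cpr" in p[1:-1] and "witnessed" not in p:
                expect += np.prod([fit.coefficient(v, u)
                                   for u, v in zip(p[:-1], p[1:])])
        assert abs(eff.effect - expect) < 1e-14

    def test_exclusion_monotone_when_products_share_sign(self, default_dag):
        rng = np.random.default_rng(11)
        fit = manual_fit(default_dag, random_b(default_dag, rng, 0.05, 0.5))
        for m in default_dag.mediators:
            ic = tuple(default_dag.intermediate_confounders(m))
            if not ic:
                continue
            full = pathway_effect(fit, m).effect
            excl = pathway_effect(fit, m, ic).effect
            assert abs(excl) <= abs(full) + 1e-15

    def test_unknown_mediator_raises(self, default_dag):
        fit = manual_fit(default_dag, random_b(default_dag,
                                               np.random.default_rng(0)))
        with pytest.raises(ValueError, match="unknown mediator"):
            pathway_effect(fit, "not_a_node")

    def test_generator_truth_recovered(self, small_config, small_table,
                                       default_dag):
        """Fitted through-mediator effects sit within 3 SEs of the
        path-traced generating values."""
        fit = pm.fit_ml(pm.binarize_sep(small_table, "MA_vs_rest"), default_dag,
                        compute_indices=False)
        truth = path_effects_from_b(default_dag,
                                    pm.true_b_matrix(small_config, default_dag))
        for m in default_dag.mediators:
            eff = pathway_effect(fit, m)
            assert abs(eff.effect - truth[f"through_{m}"]) < 3.5 * eff.se, m


class TestProportions:
    def test_printed_style_ratio(self):
        assert abs(pm.mediation_proportion(-0.005, -0.032) - 15.625) < 1e-12

    def test_limits(self):
        assert pm.mediation_proportion(0.0, -0.03) == 0.0
        assert pm.mediation_proportion(-0.03, -0.03) == 100.0

    def test_zero_total_raises(self):
        with pytest.raises(ZeroDivisionError):
            pm.mediation_proportion(0.01, 0.0)


class TestDeltaCi:
    def test_single_edge_se_equals_coefficient_se(self, default_dag):
        rng = np.random.default_rng(3)
        index = _parameterize(default_dag)
        V = np.diag(rng.uniform(0.5, 2.0, len(index)))
        fit = manual_fit(default_dag, random_b(default_dag, rng), V)
        eff = pathway_effect(fit, "__direct__")
        i = index[("B", "surv_discharge", "sep_binary")]
        assert abs(eff.se - np.sqrt(V[i, i])) < 1e-14

    def test_two_edge_chain_closed_form(self):
        """SE^2(a*b) = b^2 var(a) + a^2 var(b) + 2ab cov(a,b)."""
        dag = pm.DagSpec(nodes=["x", "m", "y"],
                         edges=[("x", "m"), ("m", "y")], covariates=["age"])
        a, b = 0.5, 0.4
        B = np.array([[0, 0, 0], [a, 0, 0], [0, b, 0]])
        index = _parameterize(dag)
        ia, ib = index[("B", "m", "x")], index[("B", "y", "m")]
        V = np.zeros((len(index), len(index)))
        V[ia, ia], V[ib, ib] = 0.01, 0.02
        V[ia, ib] = V[ib, ia] = 0.004
        fit = manual_fit(dag, B, V)
        eff = pathway_effect(fit, "m")
        expect = np.sqrt(b * b * 0.01 + a * a * 0.02 + 2 * a * b * 0.004)
        assert abs(eff.se - expect) < 1e-14

    def test_delta_vs_bootstrap_endpoints(self, default_dag):
        """Delta and percentile-bootstrap CIs for a pathway effect agree
        within 15% relative at n = 20 000."""
        cfg = pm.default_config(n_per_group=scaled_groups(20000), seed=14)
        tab = pm.binarize_sep(pm.generate_registry(cfg), "MA_vs_rest")
        fit = pm.fit_ml(tab, default_dag, compute_indices=False)
        eff = pathway_effect(fit, "witnessed")
        boot = pm.bootstrap_ci(tab, default_dag, "witnessed",
                               n_boot=2000, seed=15)
        width = eff.ucl - eff.lcl
        for d_end, b_end in zip((eff.lcl, eff.ucl), boot["effect"]):
            assert abs(d_end - b_end) <= 0.15 * width


class TestBootstrap:
    def test_deterministic_under_seed(self, default_dag):
        cfg = pm.default_config(n_per_group=scaled_groups(5000), seed=20)
        tab = pm.binarize_sep(pm.generate_registry(cfg), "MA_vs_rest")
        a = pm.bootstrap_ci(tab, default_dag, "ed_level12", n_boot=200, seed=9)
        b = pm.bootstrap_ci(tab, default_dag, "ed_level12", n_boot=200, seed=9)
        assert a == b

    def test_structural_null_covered(self, default_dag):
        """With the ED-level edges zeroed in the generator, the bootstrap CI
        for the ED-level pathway covers 0."""
        cfg = pm.default_config(n_per_group=scaled_groups(10000), seed=23)
        cfg.structural["ed_level12"].coeffs["sep_binary"] = 0.0
        tab = pm.binarize_sep(pm.generate_registry(cfg), "MA_vs_rest")
        ci = pm.bootstrap_ci(tab, default_dag, "ed_level12", n_boot=400, seed=2)
        lo, hi = ci["effect"]
        assert lo <= 0.0 <= hi

    def test_minimum_replicates_enforced(self, small_table, default_dag):
        with pytest.raises(ValueError, match="200"):
            pm.bootstrap_ci(small_table, default_dag, "witnessed",
                            n_boot=50, seed=0)


def test_mediation_table_shape(small_fit):
    tab = pm.mediation_table(small_fit)
    names = list(tab["pathway"])
    assert names[0] == "Total" and names[-1] == "Direct"
    assert "witnessed" in names
    assert "bystander_cpr but not through witnessed" in names
    assert "shockable but not through witnessed or bystander_cpr" in names
    assert np.isnan(tab.loc[0, "proportion"])      # no proportion for Total
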