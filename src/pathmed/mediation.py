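"""Pathway-specific mediation effects by the product-of-coefficients approach.

Every simple directed pathway from the exposure to the outcome carries an
effect equal to the product of its edge coefficients; pathway-set effects are
sums of such products.  The "through M" effect sums all pathways containing
mediator M; the "through M but not through its intermediate confounders"
variant drops pathways that also visit any exposure-affected variable
influencing both M and the outcome (in a recursive DAG: M's mediator
parents), leaving only routes entering M straight from the exposure.  The
mediation proportion is 100 * (pathway effect) / (total effect), where the
total effect is the reduced-form exposure -> outcome element of (I-B)^-1.

Because "through M" sets overlap across mediators, their proportions are not
required to sum to 100%; the exact decomposition identity is
total = direct + sum over all simple indirect pathways, which holds to
machine precision and is used as an internal invariant.

Standard errors come from the multivariate delta method: pathway-set effects
are multilinear in the free path coefficients, so their gradient is available
in closed form and combines with the fitted parameter covariance (robust by
default).  A nonparametric bootstrap of the whole fit is provided as an
alternative interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dag import DagSpec
from .sem import PathModelFit, fit_ml

Z95 = stats.norm.ppf(0.975)


@dataclass
class Pathway:
    nodes: list[str]

    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes[:-1], self.nodes[1:]))


@dataclass
class PathwayEffect:
    label: str
    through: str | None           # None = total or direct
    exclude: tuple[str, ...]
    effect: float
    se: float
    lcl: float
    ucl: float
    proportion: float | None      # percent of the total effect
    proportion_lcl: float | None
    proportion_ucl: float | None
    n_paths: int


def enumerate_paths(dag: DagSpec, source: str | None = None,
                    target: str | None = None) -> list[Pathway]:
    """All simple directed paths exposure -> ... -> outcome.

    Deterministic: sorted lexicographically by node sequence.
    """
    source = source or dag.exposure
    target = target or dag.outcome
    for v in (source, target):
        if v not in dag.nodes:
            raise ValueError(f"{v!r} is not a node of the DAG")
    raw = nx.all_simple_paths(dag.graph(), source, target)
    return [Pathway(list(p)) for p in sorted(raw)]


def _path_product(fit: PathModelFit, path: Pathway) -> float:
    out = 1.0
    for u, v in path.edges():
        out *= fit.coefficient(v, u)
    return out


def _select_paths(paths: list[Pathway], through: str | None,
                  exclude: tuple[str, ...]) -> list[Pathway]:
    sel = []
    for p in paths:
        inner = set(p.nodes[1:-1])
        if through is not None and through not in inner:
            continue
        if inner & set(exclude):
            continue
        sel.append(p)
    return sel


def _effect_and_gradient(fit: PathModelFit,
                         paths: list[Pathway]) -> tuple[float, np.ndarray]:
    """Sum of path products and its gradient w.r.t. all free parameters."""
    grad = np.zeros(len(fit.param_index))
    total = 0.0
    for p in paths:
        edges = p.edges()
        coefs = [fit.coefficient(v, u) for u, v in edges]
        prod = float(np.prod(coefs))
        total += prod
        for m, (u, v) in enumerate(edges):
            partial = 1.0
            for mm, c in enumerate(coefs):
                if mm != m:
                    partial *= c
            grad[fit.param_index[("B", v, u)]] += partial
    return total, grad


def total_and_direct(fit: PathModelFit, source: str | None = None,
                     target: str | None = None) -> dict[str, float]:
    """Reduced-form total effect and single-edge direct effect.

    The identity total = direct + sum of indirect path products holds to
    numerical precision by construction and is asserted here.
    """
    dag = fit.dag
    source = source or dag.exposure
    target = target or dag.outcome
    k = len(dag.nodes)
    A = np.linalg.inv(np.eye(k) - fit.B)
    tau = float(A[dag.nodes.index(target), dag.nodes.index(source)])
    try:
        delta = fit.coefficient(target, source)
    except (ValueError, KeyError):
        delta = 0.0
    paths = enumerate_paths(dag, source, target)
    indirect = sum(_path_product(fit, p) for p in paths if len(p.nodes) > 2)
    if abs(tau - (delta + indirect)) > 1e-10 * max(1.0, abs(tau)):
        raise AssertionError("path decomposition identity violated")
    return {"total": tau, "direct": delta}


def mediation_proportion(theta: float, tau: float) -> float:
    """Pathway effect as a percent of the total effect; undefined at tau=0."""
    if tau == 0.0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    return 100.0 * theta / tau


def pathway_effect(fit: PathModelFit,
                   through: str | None = None,
                   exclude: tuple[str, ...] | list[str] = (),
                   label: str | None = None,
                   alpha: float = 0.05) -> PathwayEffect:
    """Product-of-coefficients effect for a pathway selector, with delta CI.

    `through=None, exclude=()` gives the total effect; `through='__direct__'`
    the direct effect.  Otherwise all exposure -> outcome pathways containing
    `through` and avoiding every node in `exclude` are summed.
    """
    dag = fit.dag
    exclude = tuple(exclude)
    for m in ((through,) if through and through != "__direct__" else ()) + exclude:
        if m not in dag.mediators:
            raise ValueError(f"unknown mediator {m!r}")
    paths = enumerate_paths(dag)
    tau, tau_grad = _effect_and_gradient(fit, paths)
    z = stats.norm.ppf(1 - alpha / 2)

    if through == "__direct__":
        sel = [p for p in paths if len(p.nodes) == 2]
        label = label or "Direct"
    elif through is None:
        sel = paths
        label = label or "Total"
    else:
        sel = _select_paths(paths, through, exclude)
        label = label or (through if not exclude
                          else f"{through} excluding {'+'.join(exclude)}")
    theta, grad = _effect_and_gradient(fit, sel)
    V = fit.vcov
    se = float(np.sqrt(grad @ V @ grad))
    prop = prop_l = prop_u = None
    if through is not None and tau != 0.0:
        prop = mediation_proportion(theta, tau)
        # delta method on the ratio theta/tau
        g = (tau * grad - theta * tau_grad) / tau ** 2
        prop_se = 100.0 * float(np.sqrt(g @ V @ g))
        prop_l, prop_u = prop - z * prop_se, prop + z * prop_se
    return PathwayEffect(
        label=label, through=None if through in (None, "__direct__") else through,
        exclude=exclude, effect=theta, se=se,
        lcl=theta - z * se, ucl=theta + z * se,
        proportion=prop, proportion_lcl=prop_l, proportion_ucl=prop_u,
        n_paths=len(sel))


def delta_ci(fit: PathModelFit, through: str | None = None,
             exclude: tuple[str, ...] = (), alpha: float = 0.05) -> PathwayEffect:
    """Alias for `pathway_effect` emphasizing the interval construction."""
    return pathway_effect(fit, through, exclude, alpha=alpha)


def mediation_table(fit: PathModelFit,
                    suppress_nonsignificant: bool = True) -> pd.DataFrame:
    """Decomposition table: total, per-mediator pathways (with
    intermediate-confounder exclusion variants), and the direct effect.

    Proportions are suppressed (NaN) when the underlying effect's 95% CI
    covers zero, mirroring the convention of not reporting proportions for
    nonsignificant estimates.
    """
    dag = fit.dag
    rows: list[PathwayEffect] = [pathway_effect(fit, None)]
    for m in dag.mediators:
        rows.append(pathway_effect(fit, m))
        ic = dag.intermediate_confounders(m)
        if ic:
            rows.append(pathway_effect(
                fit, m, tuple(ic),
                label=f"{m} but not through {' or '.join(ic)}"))
    rows.append(pathway_effect(fit, "__direct__"))
    recs = []
    for r in rows:
        sig = not (r.lcl <= 0.0 <= r.ucl)
        show = (r.proportion is not None and
                (sig or not suppress_nonsignificant))
        recs.append({
            "pathway": r.label, "effect": r.effect, "se": r.se,
            "lcl": r.lcl, "ucl": r.ucl,
            "proportion": r.proportion if show else np.nan,
            "proportion_lcl": r.proportion_lcl if show else np.nan,
            "proportion_ucl": r.proportion_ucl if show else np.nan,
            "n_paths": r.n_paths,
        })
    # the direct row: proportion relative to total (shown when significant)
    tot = rows[0].effect
    direct = rows[-1]
    if tot != 0.0 and not (direct.lcl <= 0.0 <= direct.ucl):
        recs[-1]["proportion"] = mediation_proportion(direct.effect, tot)
    return pd.DataFrame(recs)


def path_effects_from_b(dag: DagSpec, B: np.ndarray) -> dict[str, float]:
    """Closed-form path-traced effects from a coefficient matrix.

    Pure path tracing on B (rows/columns in `dag.nodes` order): total and
    direct effects plus every "through M" / "through M excluding its
    intermediate confounders" sum.  Serves as the generating-truth oracle
    when B holds the data-generating coefficients.
    """
    paths = enumerate_paths(dag)
    idx = {n: i for i, n in enumerate(dag.nodes)}

    def product(p: Pathway) -> float:
        out = 1.0
        for u, v in p.edges():
            out *= B[idx[v], idx[u]]
        return out

    out: dict[str, float] = {
        "total": float(sum(product(p) for p in paths)),
        "direct": float(sum(product(p) for p in paths if len(p.nodes) == 2)),
    }
    for m in dag.mediators:
        out[f"through_{m}"] = float(sum(
            product(p) for p in _select_paths(paths, m, ())))
        ic = tuple(dag.intermediate_confounders(m))
        if ic:
            out[f"through_{m}_excl"] = float(sum(
                product(p) for p in _select_paths(paths, m, ic)))
    return out


def bootstrap_ci(data, spec: DagSpec,
                 through: str | None = None,
                 exclude: tuple[str, ...] = (),
                 n_boot: int = 500, seed: int = 0,
                 alpha: float = 0.05,
                 max_failures: float = 0.05) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap for a pathway effect and its mediation proportion.

    Resamples subjects with replacement and refits the whole path model per
    resample (closed-form fit; no polish needed since it is the exact ML
    solution).  Deterministic under `seed`.
    """
    if n_boot < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    df = data.data if hasattr(data, "data") else data
    cols = list(spec.covariates) + list(spec.nodes)
    Z = df[cols].to_numpy(dtype=float)
    n = len(Z)
    rng = np.random.default_rng(seed)
    effs, props = [], []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        Sb = np.cov(Z[idx], rowvar=False)
        try:
            fb = fit_ml(None, spec, S=Sb, N=n, robust=False, refine=False,
                        compute_indices=False)
            eff = pathway_effect(fb, through, exclude)
        except (ValueError, np.linalg.LinAlgError, ZeroDivisionError):
            failures += 1
            continue
        effs.append(eff.effect)
        if eff.proportion is not None:
            props.append(eff.proportion)
    if failures > max_failures * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = {"effect": (float(np.percentile(effs, lo)),
                      float(np.percentile(effs, hi)))}
    if props:
        out["proportion"] = (float(np.percentile(props, lo)),
                             float(np.percentile(props, hi)))
    return out
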