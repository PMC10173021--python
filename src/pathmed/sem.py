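"""Recursive observed-variable path model fitted by maximum likelihood.

The model is the LISREL-form simultaneous-equation system

    y = B y + G x + zeta,   Cov(zeta) = Psi (diagonal),  Cov(x) = Phi (free)

with y the endogenous block (exposure, mediators, outcome; binary variables
modeled on the linear-probability scale) and x the exogenous confounders.
B is strictly lower triangular in temporal order (recursive), so the reduced
form is y = (I-B)^-1 (G x + zeta) and the model-implied covariance of the
stacked vector (x, y) is

    Sigma = [ Phi,            Phi G' A' ]          A = (I-B)^-1
            [ A G Phi,  A (G Phi G' + Psi) A' ]

Estimation minimizes the ML discrepancy
F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p over the free parameters.
For a recursive model with diagonal Psi the likelihood factorizes along the
DAG, so the minimizer is available in closed form as per-equation OLS
computed from S; a quasi-Newton polish from that start verifies the optimum
(gradient norm < 1e-6).  "Robust ML" means: ML point estimates, sandwich
standard errors from per-observation estimating-equation scores, and a
Satorra-Bentler-type mean scaling of the chi-square computed from estimated
fourth moments.

Conventions (software packages differ): S uses the N-1 divisor; the test
statistic is T = (N-1) * F at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dag import DagSpec
from .registry import RegistryTable

GRAD_TOL = 1e-6

ParamKey = tuple[str, str, str]  # ("B"|"G"|"psi", child, parent-or-"")


@dataclass
class FitIndices:
    rmsea: float
    srmr: float
    gfi: float
    cfi: float


@dataclass
class PathModelFit:
    """Fitted path model: coefficients, covariances, discrepancy and indices."""

    dag: DagSpec
    var_names: list[str]            # covariates then endogenous nodes
    B: np.ndarray                   # k x k, strictly lower triangular
    G: np.ndarray                   # k x q exogenous coefficients
    Psi: np.ndarray                 # k residual variances (diagonal)
    Phi: np.ndarray                 # q x q exogenous covariance
    S: np.ndarray                   # sample covariance, p x p
    Sigma: np.ndarray               # model-implied covariance
    N: int
    F_ML: float
    T: float
    df: int
    scaling: float                  # Satorra-Bentler-type mean correction c
    param_index: dict[ParamKey, int]
    vcov: np.ndarray                # free-coefficient covariance (robust or naive)
    vcov_naive: np.ndarray
    converged: bool
    indices: FitIndices | None = None
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------ accessors
    @property
    def nodes(self) -> list[str]:
        return self.dag.nodes

    def coefficient(self, child: str, parent: str) -> float:
        key = ("B", child, parent) if ("B", child, parent) in self.param_index \
            else ("G", child, parent)
        kind, i, j = self._positions(key)
        return float(self.B[i, j] if kind == "B" else self.G[i, j])

    def _positions(self, key: ParamKey) -> tuple[str, int, int]:
        kind, child, parent = key
        ci = self.dag.nodes.index(child)
        if kind == "B":
            return "B", ci, self.dag.nodes.index(parent)
        return "G", ci, self.dag.covariates.index(parent)

    def se(self, child: str, parent: str) -> float:
        key = ("B", child, parent) if ("B", child, parent) in self.param_index \
            else ("G", child, parent)
        i = self.param_index[key]
        return float(np.sqrt(self.vcov[i, i]))

    def free_b_params(self) -> list[ParamKey]:
        return [k for k in self.param_index if k[0] == "B"]

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for (kind, child, parent), i in self.param_index.items():
            if kind == "psi":
                continue
            est = self.coefficient(child, parent)
            se = float(np.sqrt(self.vcov[i, i]))
            rows.append({"child": child, "parent": parent, "estimate": est,
                         "se": se, "lcl": est - 1.959963984540054 * se,
                         "ucl": est + 1.959963984540054 * se})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        idx = self.indices
        return {
            "nodes": self.dag.nodes,
            "covariates": self.dag.covariates,
            "coefficients": {f"{c}~{p}": self.coefficient(c, p)
                             for (kind, c, p) in self.param_index if kind != "psi"},
            "residual_variances": {n: float(self.Psi[i])
                                   for i, n in enumerate(self.dag.nodes)},
            "N": int(self.N), "F_ML": float(self.F_ML), "T": float(self.T),
            "df": int(self.df), "scaling": float(self.scaling),
            "converged": bool(self.converged),
            "fit_indices": None if idx is None else vars(idx),
        }


# ------------------------------------------------------- covariance algebra

def implied_covariance(B: np.ndarray, G: np.ndarray, Psi: np.ndarray,
                       Phi: np.ndarray) -> np.ndarray:
    """Model-implied covariance of (x, y) from the reduced form.

    Psi may be a length-k vector of residual variances or a k x k diagonal
    matrix.  Exact matrix identity; (I-B) is invertible because B is strictly
    lower triangular.
    """
    B = np.asarray(B, dtype=float)
    G = np.asarray(G, dtype=float)
    Phi = np.asarray(Phi, dtype=float)
    Psi = np.asarray(Psi, dtype=float)
    if Psi.ndim == 1:
        Psi = np.diag(Psi)
    k = B.shape[0]
    q = Phi.shape[0]
    if B.shape != (k, k) or G.shape != (k, q) or Psi.shape != (k, k):
        raise ValueError("dimension mismatch among B, G, Psi, Phi")
    A = np.linalg.inv(np.eye(k) - B)
    W = G @ Phi @ G.T + Psi
    Syy = A @ W @ A.T
    Sxy = Phi @ G.T @ A.T
    top = np.hstack([Phi, Sxy])
    bottom = np.hstack([Sxy.T, Syy])
    return np.vstack([top, bottom])


def _f_ml(S: np.ndarray, Sigma: np.ndarray, logdet_S: float) -> float:
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(np.linalg.solve(Sigma, S))) \
        - logdet_S - S.shape[0]


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix D with vec(A) = D vech(A) for symmetric A."""
    rows = p * p
    cols = p * (p + 1) // 2
    D = np.zeros((rows, cols))
    # column order matches np.tril_indices (row-major over the lower triangle)
    for col, (i, j) in enumerate(zip(*np.tril_indices(p))):
        D[i * p + j, col] = 1.0
        D[j * p + i, col] = 1.0
    return D


def _vech(A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    return A[np.tril_indices(p)]


# ----------------------------------------------------------------- fitting

def _parameterize(spec: DagSpec) -> dict[ParamKey, int]:
    """Free-parameter index: G then B per equation (temporal order), then psi."""
    index: dict[ParamKey, int] = {}
    i = 0
    for node in spec.nodes:
        for c in spec.covariate_parents(node):
            index[("G", node, c)] = i
            i += 1
        for parent in spec.parents(node):
            index[("B", node, parent)] = i
            i += 1
    for node in spec.nodes:
        index[("psi", node, "")] = i
        i += 1
    return index


def _ols_from_cov(S: np.ndarray, spec: DagSpec,
                  var_names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form per-equation OLS estimates computed from S."""
    pos = {v: i for i, v in enumerate(var_names)}
    k = len(spec.nodes)
    q = len(spec.covariates)
    B = np.zeros((k, k))
    G = np.zeros((k, q))
    psi = np.zeros(k)
    for ji, node in enumerate(spec.nodes):
        preds = spec.covariate_parents(node) + spec.parents(node)
        yi = pos[node]
        if not preds:
            psi[ji] = S[yi, yi]
            continue
        pi = [pos[v] for v in preds]
        beta = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, yi])
        psi[ji] = S[yi, yi] - S[yi, pi] @ beta
        for v, b in zip(preds, beta):
            if v in spec.covariates:
                G[ji, spec.covariates.index(v)] = b
            else:
                B[ji, spec.nodes.index(v)] = b
    return B, G, psi


def _unpack(theta: np.ndarray, spec: DagSpec,
            index: dict[ParamKey, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = len(spec.nodes)
    q = len(spec.covariates)
    B = np.zeros((k, k))
    G = np.zeros((k, q))
    psi = np.zeros(k)
    for (kind, child, parent), i in index.items():
        ci = spec.nodes.index(child)
        if kind == "B":
            B[ci, spec.nodes.index(parent)] = theta[i]
        elif kind == "G":
            G[ci, spec.covariates.index(parent)] = theta[i]
        else:
            psi[ci] = theta[i]
    return B, G, psi


def _pack(B: np.ndarray, G: np.ndarray, psi: np.ndarray, spec: DagSpec,
          index: dict[ParamKey, int]) -> np.ndarray:
    theta = np.zeros(len(index))
    for (kind, child, parent), i in index.items():
        ci = spec.nodes.index(child)
        if kind == "B":
            theta[i] = B[ci, spec.nodes.index(parent)]
        elif kind == "G":
            theta[i] = G[ci, spec.covariates.index(parent)]
        else:
            theta[i] = psi[ci]
    return theta


def _gradient(theta: np.ndarray, S: np.ndarray, Phi: np.ndarray,
              spec: DagSpec, index: dict[ParamKey, int],
              logdet_S: float) -> tuple[float, np.ndarray]:
    """F_ML and its analytic gradient at theta."""
    k = len(spec.nodes)
    q = len(spec.covariates)
    B, G, psi = _unpack(theta, spec, index)
    if np.any(psi <= 0):
        return np.inf, np.zeros_like(theta)
    Sigma = implied_covariance(B, G, psi, Phi)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    Sinv = np.linalg.inv(Sigma)
    F = logdet + float(np.trace(Sinv @ S)) - logdet_S - S.shape[0]
    M = Sinv - Sinv @ S @ Sinv            # dF = tr(M dSigma)
    A = np.linalg.inv(np.eye(k) - B)
    W = G @ Phi @ G.T + np.diag(psi)
    AW = A @ W
    PhiGt = Phi @ G.T
    grad = np.zeros_like(theta)
    Myy = M[q:, q:]
    Mxy = M[:q, q:]
    for (kind, child, parent), i in index.items():
        ci = spec.nodes.index(child)
        if kind == "B":
            pj = spec.nodes.index(parent)
            dA = np.outer(A[:, ci], A[pj, :])
            dSyy = dA @ AW.T + AW @ dA.T
            dSxy = PhiGt @ dA.T
            grad[i] = float(np.sum(Myy * dSyy) + 2.0 * np.sum(Mxy * dSxy))
        elif kind == "G":
            cj = spec.covariates.index(parent)
            dG = np.zeros((k, q))
            dG[ci, cj] = 1.0
            AdG = A @ dG
            dW = dG @ PhiGt + PhiGt.T @ dG.T
            dSyy = A @ dW @ A.T
            dSxy = Phi @ dG.T @ A.T
            grad[i] = float(np.sum(Myy * dSyy) + 2.0 * np.sum(Mxy * dSxy))
        else:
            dSyy = np.outer(A[:, ci], A[:, ci])
            grad[i] = float(np.sum(Myy * dSyy))
    return F, grad


def _coefficient_scores(Z: np.ndarray, var_names: list[str], spec: DagSpec,
                        index: dict[ParamKey, int], B: np.ndarray,
                        G: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Per-observation estimating-equation scores for all free parameters."""
    pos = {v: i for i, v in enumerate(var_names)}
    n = Z.shape[0]
    scores = np.zeros((n, len(index)))
    for ji, node in enumerate(spec.nodes):
        preds = spec.covariate_parents(node) + spec.parents(node)
        yhat = np.zeros(n)
        for v in preds:
            coef = G[ji, spec.covariates.index(v)] if v in spec.covariates \
                else B[ji, spec.nodes.index(v)]
            yhat += coef * Z[:, pos[v]]
        resid = Z[:, pos[node]] - yhat
        for v in preds:
            key = ("G", node, v) if v in spec.covariates else ("B", node, v)
            scores[:, index[key]] = Z[:, pos[v]] * resid / psi[ji]
        scores[:, index[("psi", node, "")]] = \
            (resid ** 2 - psi[ji]) / (2.0 * psi[ji] ** 2)
    return scores


def _bread(S: np.ndarray, var_names: list[str], spec: DagSpec,
           index: dict[ParamKey, int], psi: np.ndarray) -> np.ndarray:
    """Expected negative score derivative (block diagonal per equation)."""
    pos = {v: i for i, v in enumerate(var_names)}
    P = len(index)
    Ainfo = np.zeros((P, P))
    for ji, node in enumerate(spec.nodes):
        preds = spec.covariate_parents(node) + spec.parents(node)
        keys = [("G", node, v) if v in spec.covariates else ("B", node, v)
                for v in preds]
        ii = [index[kk] for kk in keys]
        pi = [pos[v] for v in preds]
        if pi:
            Ainfo[np.ix_(ii, ii)] = S[np.ix_(pi, pi)] / psi[ji]
        Ainfo[index[("psi", node, "")], index[("psi", node, "")]] = \
            1.0 / (2.0 * psi[ji] ** 2)
    return Ainfo


def _sb_scaling(Z: np.ndarray, S: np.ndarray, Sigma: np.ndarray,
                Phi_index_offset: int, Delta: np.ndarray, df: int) -> float:
    """Satorra-Bentler mean-scaling factor c = tr(U Gamma_adf) / df."""
    if df == 0:
        return 1.0
    p = S.shape[0]
    n = Z.shape[0]
    Zt = np.ascontiguousarray((Z - Z.mean(axis=0)).T)
    il, jl = np.tril_indices(p)
    Wt = Zt[il] * Zt[jl]                  # p* x n, row-contiguous
    m = Wt.mean(axis=1)
    Gamma_adf = (Wt @ Wt.T) / n - np.outer(m, m)
    D = _duplication(p)
    Sinv = np.linalg.inv(Sigma)
    Wmat = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
    WD = Wmat @ Delta
    U = Wmat - WD @ np.linalg.solve(Delta.T @ WD, WD.T)
    return float(np.trace(U @ Gamma_adf) / df)


def _full_delta(B: np.ndarray, G: np.ndarray, psi: np.ndarray,
                Phi: np.ndarray, spec: DagSpec,
                index: dict[ParamKey, int]) -> np.ndarray:
    """d vech(Sigma) / d theta over ALL free parameters including Phi."""
    k, q = G.shape
    p = q + k
    A = np.linalg.inv(np.eye(k) - B)
    W = G @ Phi @ G.T + np.diag(psi)
    AW = A @ W
    PhiGt = Phi @ G.T
    il = np.tril_indices(p)

    def assemble(dSxx, dSxy, dSyy):
        out = np.zeros((p, p))
        out[:q, :q] = dSxx
        out[:q, q:] = dSxy
        out[q:, :q] = dSxy.T
        out[q:, q:] = dSyy
        return out[il]

    cols = []
    for (kind, child, parent), _ in sorted(index.items(), key=lambda kv: kv[1]):
        ci = spec.nodes.index(child)
        if kind == "B":
            pj = spec.nodes.index(parent)
            dA = np.outer(A[:, ci], A[pj, :])
            cols.append(assemble(np.zeros((q, q)), PhiGt @ dA.T,
                                 dA @ AW.T + AW @ dA.T))
        elif kind == "G":
            cj = spec.covariates.index(parent)
            dG = np.zeros((k, q))
            dG[ci, cj] = 1.0
            dW = dG @ PhiGt + (dG @ PhiGt).T
            cols.append(assemble(np.zeros((q, q)), Phi @ dG.T @ A.T,
                                 A @ dW @ A.T))
        else:
            cols.append(assemble(np.zeros((q, q)), np.zeros((q, k)),
                                 np.outer(A[:, ci], A[:, ci])))
    # free Phi entries (symmetric, q(q+1)/2 of them)
    for a in range(q):
        for b in range(a, q):
            dPhi = np.zeros((q, q))
            dPhi[a, b] = dPhi[b, a] = 1.0
            dSxy = dPhi @ G.T @ A.T
            dSyy = A @ G @ dPhi @ G.T @ A.T
            cols.append(assemble(dPhi, dSxy, dSyy))
    return np.column_stack(cols)


def fit_ml(data: RegistryTable | pd.DataFrame | None,
           spec: DagSpec,
           S: np.ndarray | None = None,
           N: int | None = None,
           robust: bool = True,
           refine: bool = True,
           compute_indices: bool = True) -> PathModelFit:
    """Fit the path model by ML on the covariance structure.

    Pass either a data table (rows complete on all model variables) or a
    sample covariance `S` with its `N` (robust corrections then unavailable).
    Estimates are per-equation OLS computed from S (the exact ML solution for
    a recursive model with diagonal residual covariance), verified by a
    quasi-Newton polish of F_ML when `refine` is set.
    """
    var_names = list(spec.covariates) + list(spec.nodes)
    Z = None
    if data is not None:
        df = data.data if isinstance(data, RegistryTable) else data
        missing_cols = [v for v in var_names if v not in df.columns]
        if missing_cols:
            raise ValueError(f"columns absent from data: {missing_cols}")
        Z = df[var_names].to_numpy(dtype=float)
        if np.isnan(Z).any():
            raise ValueError("missing values among model variables")
        N = Z.shape[0]
        S = np.cov(Z, rowvar=False)
    elif S is None or N is None:
        raise ValueError("provide either data or (S, N)")
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p != len(var_names):
        raise ValueError("S dimension does not match model variables")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")

    index = _parameterize(spec)
    q = len(spec.covariates)
    Phi = S[:q, :q].copy()
    B, G, psi = _ols_from_cov(S, spec, var_names)
    converged = True
    if refine:
        theta0 = _pack(B, G, psi, spec, index)
        res = minimize(lambda t: _gradient(t, S, Phi, spec, index, logdet_S),
                       theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200, "gtol": GRAD_TOL / 10})
        F0 = _gradient(theta0, S, Phi, spec, index, logdet_S)[0]
        if np.isfinite(res.fun) and res.fun < F0:
            B, G, psi = _unpack(res.x, spec, index)
        theta_hat = _pack(B, G, psi, spec, index)
        gnorm = float(np.linalg.norm(
            _gradient(theta_hat, S, Phi, spec, index, logdet_S)[1]))
        converged = gnorm < GRAD_TOL
    Sigma = implied_covariance(B, G, psi, Phi)
    F = _f_ml(S, Sigma, logdet_S)
    T = (N - 1) * F
    n_free = len(index) + q * (q + 1) // 2
    dof = p * (p + 1) // 2 - n_free
    if dof < 0:
        raise ValueError("model has more free parameters than moments")

    bread = _bread(S, var_names, spec, index, psi)
    vcov_naive = np.linalg.inv(bread) / N
    scaling = 1.0
    vcov = vcov_naive
    if robust and Z is not None:
        Zc = Z - Z.mean(axis=0)
        scores = _coefficient_scores(Zc, var_names, spec, index, B, G, psi)
        meat = scores.T @ scores / N
        binv = np.linalg.inv(bread)
        vcov = binv @ meat @ binv / N
        if dof > 0:
            Delta = _full_delta(B, G, psi, Phi, spec, index)
            scaling = _sb_scaling(Z, S, Sigma, len(index), Delta, dof)

    fit = PathModelFit(
        dag=spec, var_names=var_names, B=B, G=G, Psi=psi, Phi=Phi, S=S,
        Sigma=Sigma, N=N, F_ML=F, T=T, df=dof, scaling=scaling,
        param_index=index, vcov=vcov, vcov_naive=vcov_naive,
        converged=converged)
    if compute_indices:
        fit.indices = fit_indices(fit)
    return fit


# -------------------------------------------------------------- fit indices

def baseline_statistic(S: np.ndarray, N: int) -> tuple[float, int]:
    """Independence-model chi-square and df (all covariances zero)."""
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    F_b = float(np.sum(np.log(np.diag(S)))) - logdet_S
    return (N - 1) * F_b, p * (p - 1) // 2


def rmsea(T: float, df: int, N: int) -> float:
    """Root mean square error of approximation; 0 for a saturated model."""
    if df == 0:
        return 0.0
    return float(np.sqrt(max(T - df, 0.0) / (df * (N - 1))))


def cfi(T: float, df: int, T_b: float, df_b: int) -> float:
    """Comparative fit index against the independence baseline."""
    denom = max(T_b - df_b, T - df, 0.0)
    if df == 0 or denom == 0.0:
        return 1.0
    return float(min(max(1.0 - max(T - df, 0.0) / denom, 0.0), 1.0))


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root mean square residual.

    Residuals are standardized to the correlation metric using sample
    variances; the mean square runs over the lower triangle including the
    diagonal (so implied-variance misfit counts too).
    """
    d = np.sqrt(np.diag(S))
    R = (S - Sigma) / np.outer(d, d)
    il = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(R[il] ** 2)))


def gfi(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Goodness-of-fit index 1 - tr((Sigma^-1 S - I)^2) / tr((Sigma^-1 S)^2)."""
    SinvS = np.linalg.solve(Sigma, S)
    p = S.shape[0]
    E = SinvS - np.eye(p)
    return float(1.0 - np.trace(E @ E) / np.trace(SinvS @ SinvS))


def fit_indices(fit: PathModelFit, robust: bool = False) -> FitIndices:
    """RMSEA, SRMR, GFI and CFI for a fitted model.

    `robust` rescales both the model and baseline chi-squares by the
    Satorra-Bentler factor before RMSEA/CFI (identical when the factor is 1).
    With df = 0 the model is saturated: RMSEA is 0 and CFI is 1 by convention.
    """
    T = fit.T / fit.scaling if robust else fit.T
    T_b, df_b = baseline_statistic(fit.S, fit.N)
    if robust:
        T_b = T_b / fit.scaling
    return FitIndices(rmsea=rmsea(T, fit.df, fit.N),
                      srmr=srmr(fit.S, fit.Sigma),
                      gfi=gfi(fit.S, fit.Sigma),
                      cfi=cfi(T, fit.df, T_b, df_b))
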