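"""Logistic regression engine and registry-level epidemiological summaries.

The engine is a plain Newton-Raphson/IRLS maximizer of the Bernoulli
log-likelihood with the covariance of the estimates taken as the inverse
observed information; odds ratios are exp(coefficients) with Wald intervals.
On top of it sit the adjusted odds-ratio table across SEP levels, the
Baron-Kenny two-step mediator screen, and a descriptive (Table-1-style)
summary with standardized mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .registry import RegistryTable

MAX_ITER = 100
GRAD_TOL = 1e-8


class SeparationError(RuntimeError):
    """Raised when IRLS fails to converge (e.g. complete separation)."""


@dataclass
class LogisticFit:
    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    n: int
    loglik: float
    converged: bool
    n_iter: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(beta) with Wald confidence limits and two-sided p-values."""
        se = self.se()
        z = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(np.abs(self.beta / se))
        return pd.DataFrame({
            "term": self.names,
            "estimate": self.beta,
            "se": se,
            "or": np.exp(self.beta),
            "lcl": np.exp(self.beta - z * se),
            "ucl": np.exp(self.beta + z * se),
            "p": p,
        })

    def wald_p(self, term: str) -> float:
        i = self.names.index(term)
        return float(2 * stats.norm.sf(abs(self.beta[i] / self.se()[i])))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.beta)


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Iterates Newton steps (with step-halving on likelihood decrease) until
    the score norm drops below 1e-8.  Requires complete data and a full-rank
    design; separation or non-convergence raises, never returns silently.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("y and X have incompatible shapes")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y or X")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    names = names or [f"x{j}" for j in range(X.shape[1])]

    def loglik(b):
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    beta = np.zeros(X.shape[1])
    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        if np.linalg.norm(score) < GRAD_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halving keeps IRLS monotone near separation; tolerance is
        # relative to |loglik| so float noise cannot block full Newton steps
        scale = 1.0
        tol = 1e-9 * (1.0 + abs(ll))
        for _ in range(30):
            cand = beta + scale * step
            if loglik(cand) >= ll - tol:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = loglik(beta)
        if np.abs(beta).max() > 30.0:
            raise SeparationError(
                "coefficients diverging; data are likely separated")
    if not converged:
        p = expit(X @ beta)
        if np.linalg.norm(X.T @ (y - p)) >= GRAD_TOL:
            raise SeparationError(f"IRLS did not converge in {MAX_ITER} iterations")
        converged = True
    p = expit(X @ beta)
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return LogisticFit(names, beta, cov, len(y), ll, converged, it)


def _design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for t in terms:
        cols.append(table[t].to_numpy(dtype=float))
        names.append(t)
    return np.column_stack(cols), names


def fit_logistic_formula(table: pd.DataFrame, outcome: str,
                         terms: list[str]) -> LogisticFit:
    """Logistic fit of `outcome` on intercept + `terms` from a data frame."""
    X, names = _design(table, terms)
    return fit_logistic(table[outcome].to_numpy(dtype=float), X, names)


# -------------------------------------------------------------- OR tables

def adjusted_or_table(table: RegistryTable | pd.DataFrame,
                      outcome: str,
                      exposure: str = "sep_level",
                      confounders: list[str] | None = None,
                      reference: str = "NHI_Q1") -> pd.DataFrame:
    """Odds ratios of `outcome` per exposure level versus a reference level.

    Indicator-codes the exposure with `reference` as baseline and adjusts for
    the given confounders (empty list -> crude table from the same call).
    """
    df = table.data if isinstance(table, RegistryTable) else table
    confounders = list(confounders) if confounders is not None else []
    levels = [l for l in df[exposure].astype("category").cat.categories
              if l != reference]
    if reference not in set(df[exposure]):
        raise ValueError(f"reference level {reference!r} absent from {exposure}")
    work = pd.DataFrame(index=df.index)
    ind_names = []
    for lev in levels:
        name = f"{exposure}[{lev}]"
        work[name] = (df[exposure] == lev).astype(float)
        ind_names.append(name)
    for c in confounders:
        work[c] = df[c].astype(float)
    work[outcome] = df[outcome].astype(float)
    fit = fit_logistic_formula(work, outcome, ind_names + confounders)
    tab = fit.odds_ratios()
    tab = tab[tab["term"].isin(ind_names)].reset_index(drop=True)
    tab.insert(0, "level", levels)
    tab.insert(1, "reference", reference)
    return tab.drop(columns="term")


# ------------------------------------------------------- mediator screening

@dataclass
class MediatorScreenResult:
    mediator: str
    step1_estimate: float       # exposure -> mediator (adjusted)
    step1_p: float
    step2_estimate: float       # mediator -> outcome | exposure + confounders
    step2_p: float
    exposure_without: float     # exposure coefficient, outcome model sans mediator
    exposure_with: float        # ... with the mediator included
    is_mediator: bool

    @property
    def attenuation(self) -> float:
        """Descriptive change in the exposure coefficient when the mediator
        enters the outcome model (classic step-4 attenuation, not tested)."""
        return self.exposure_without - self.exposure_with


def baron_kenny_screen(table: RegistryTable | pd.DataFrame,
                       mediator: str,
                       outcome: str = "surv_discharge",
                       exposure: str = "sep_binary",
                       confounders: list[str] | None = None,
                       alpha: float = 0.05) -> MediatorScreenResult:
    """Two-step mediator screen with multivariable logistic regressions.

    A candidate passes when (1) the exposure predicts the mediator and
    (2) the mediator predicts the outcome given exposure and confounders,
    both at the two-sided `alpha` level.
    """
    df = table.data if isinstance(table, RegistryTable) else table
    confounders = confounders if confounders is not None else \
        ["age", "sex", "diabetes", "hypertension", "metropolitan"]
    f1 = fit_logistic_formula(df, mediator, [exposure] + confounders)
    f2 = fit_logistic_formula(df, outcome, [mediator, exposure] + confounders)
    f0 = fit_logistic_formula(df, outcome, [exposure] + confounders)
    s1_est = f1.beta[f1.names.index(exposure)]
    s1_p = f1.wald_p(exposure)
    s2_est = f2.beta[f2.names.index(mediator)]
    s2_p = f2.wald_p(mediator)
    return MediatorScreenResult(
        mediator=mediator,
        step1_estimate=float(s1_est), step1_p=s1_p,
        step2_estimate=float(s2_est), step2_p=s2_p,
        exposure_without=float(f0.beta[f0.names.index(exposure)]),
        exposure_with=float(f2.beta[f2.names.index(exposure)]),
        is_mediator=bool(s1_p < alpha and s2_p < alpha),
    )


def screen_mediators(table: RegistryTable | pd.DataFrame,
                     mediators: list[str],
                     **kwargs) -> pd.DataFrame:
    """Run the Baron-Kenny screen over a candidate list; one row per candidate."""
    rows = [baron_kenny_screen(table, m, **kwargs) for m in mediators]
    return pd.DataFrame([{
        "mediator": r.mediator,
        "step1_estimate": r.step1_estimate, "step1_p": r.step1_p,
        "step2_estimate": r.step2_estimate, "step2_p": r.step2_p,
        "attenuation": r.attenuation, "is_mediator": r.is_mediator,
    } for r in rows])


# ------------------------------------------------------------- descriptives

def smd_binary(p1: float, p2: float) -> float:
    """Standardized mean difference for proportions (pooled-variance form)."""
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    return 0.0 if denom == 0 else (p1 - p2) / denom


def smd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    denom = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    return 0.0 if denom == 0 else (m1 - m2) / denom


def descriptive_table(table: RegistryTable,
                      group: str = "sep_level",
                      reference: str = "NHI_Q1") -> pd.DataFrame:
    """Per-group descriptive summary in the style of a cohort Table 1.

    Binary columns: count and percentage (1 decimal) per group, SMD versus
    the reference group, chi-square p-value.  Continuous columns: median
    (IQR), SMD from means/SDs, Kruskal-Wallis p-value.
    """
    df = table.data
    if group not in df.columns:
        raise ValueError(f"grouping column {group!r} absent")
    levels = list(df[group].astype("category").cat.categories)
    if any((df[group] == g).sum() == 0 for g in levels):
        raise ValueError("empty group level")
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not a group level")
    rows = []
    skip = {group, "sep_binary"}
    for col in df.columns:
        if col in skip:
            continue
        info = table.codebook.get(col, {})
        sub = {g: df.loc[df[group] == g, col].dropna() for g in levels}
        if info.get("type") == "continuous":
            stat_p = stats.kruskal(*[sub[g] for g in levels]).pvalue
            for g in levels:
                s = sub[g]
                rows.append({
                    "variable": col, "group": g, "n": len(s),
                    "summary": f"{s.median():.0f} ({s.quantile(.25):.0f}-"
                               f"{s.quantile(.75):.0f})",
                    "value": float(s.median()),
                    "smd_vs_ref": smd_continuous(
                        s.mean(), s.std(), sub[reference].mean(),
                        sub[reference].std()),
                    "p": stat_p,
                })
        elif info.get("type") == "binary":
            counts = np.array([[int(sub[g].sum()), int(len(sub[g]) - sub[g].sum())]
                               for g in levels])
            if (counts.sum(axis=0) == 0).any():
                stat_p = np.nan
            else:
                stat_p = stats.chi2_contingency(counts).pvalue
            for g in levels:
                k, n = int(sub[g].sum()), len(sub[g])
                pct = round(100.0 * k / n, 1)
                rows.append({
                    "variable": col, "group": g, "n": n,
                    "summary": f"{k} ({pct})", "value": pct,
                    "smd_vs_ref": smd_binary(k / n, sub[reference].mean()),
                    "p": stat_p,
                })
    return pd.DataFrame(rows)
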