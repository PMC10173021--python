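"""Variable coding, SEP binarization, and stochastic-regression imputation.

Missing mediator cells are completed by single stochastic regression
imputation: one logistic model per missing-prone column fitted on complete
cases, each missing cell then drawn as Bernoulli(predicted probability) -
never thresholded, so imputed columns keep binomial variability.  Columns are
completed in temporal order, each model conditioning on confounders, the
exposure, and the already-completed upstream mediators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import LogisticFit, SeparationError, fit_logistic
from .registry import SEP_LEVELS, RegistryTable

#: the four SEP binarization cutoffs; the low group always contains MA
SCHEMES: dict[str, list[str]] = {
    "MA_vs_rest": ["MA"],
    "MA+Q4": ["MA", "NHI_Q4"],
    "MA+Q3+Q4": ["MA", "NHI_Q3", "NHI_Q4"],
    "MA+Q2+Q3+Q4": ["MA", "NHI_Q2", "NHI_Q3", "NHI_Q4"],
}

#: temporal completion order of the missing-prone mediators
IMPUTATION_ORDER = ["public_location", "witnessed", "bystander_cpr",
                    "bystander_aed", "rti_lt8", "shockable"]

BASE_PREDICTORS = ["sep_binary", "age", "sex", "diabetes", "hypertension",
                   "metropolitan"]


@dataclass
class BinarizationScheme:
    cutoff_id: str
    low_group_labels: list[str]

    @classmethod
    def from_id(cls, cutoff_id: str) -> "BinarizationScheme":
        if cutoff_id not in SCHEMES:
            raise ValueError(f"unknown scheme {cutoff_id!r}; "
                             f"choose from {sorted(SCHEMES)}")
        return cls(cutoff_id, list(SCHEMES[cutoff_id]))


def binarize_sep(table: RegistryTable,
                 scheme: BinarizationScheme | str) -> RegistryTable:
    """Set sep_binary = 1 for subjects whose SEP level is in the low group."""
    if isinstance(scheme, str):
        scheme = BinarizationScheme.from_id(scheme)
    out = table.copy()
    levels = out.data["sep_level"].astype(str)
    unknown = sorted(set(levels) - set(SEP_LEVELS))
    if unknown:
        raise ValueError(f"unknown SEP labels: {unknown}")
    out.data["sep_binary"] = levels.isin(scheme.low_group_labels).astype(np.int8)
    out.meta["binarization"] = scheme.cutoff_id
    return out


@dataclass
class ImputationModel:
    target: str
    predictors: list[str]
    fit: LogisticFit = field(repr=False)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = np.column_stack([np.ones(len(df))] +
                            [df[p].to_numpy(dtype=float) for p in self.predictors])
        return self.fit.predict(X)


def fit_imputation_models(table: RegistryTable,
                          predictors: dict[str, list[str]] | None = None,
                          min_complete: int = 50) -> list[ImputationModel]:
    """Fit one complete-case logistic model per column with missing cells.

    Default predictor set per target: confounders + binarized SEP + every
    missing-prone mediator upstream of the target in temporal order (a
    missing-at-random completion model).  Complete cases for a target are the
    rows where the target and all its predictors are observed.
    """
    df = table.data
    models: list[ImputationModel] = []
    for i, target in enumerate(IMPUTATION_ORDER):
        if target not in df.columns or not df[target].isna().any():
            continue
        if predictors is not None and target in predictors:
            preds = list(predictors[target])
        else:
            preds = BASE_PREDICTORS + [c for c in IMPUTATION_ORDER[:i]
                                       if c in df.columns]
        if target in preds:
            raise ValueError(f"target {target!r} among its own predictors")
        cc = df[[target] + preds].dropna()
        if len(cc) < min_complete:
            raise ValueError(
                f"only {len(cc)} complete cases for {target!r} "
                f"(floor {min_complete})")
        X = np.column_stack([np.ones(len(cc))] +
                            [cc[p].to_numpy(dtype=float) for p in preds])
        try:
            fit = fit_logistic(cc[target].to_numpy(dtype=float), X,
                               ["intercept"] + preds)
        except SeparationError as exc:
            raise SeparationError(
                f"imputation model for {target!r} failed: {exc}") from exc
        models.append(ImputationModel(target, preds, fit))
    return models


def impute_stochastic(table: RegistryTable,
                      models: list[ImputationModel],
                      seed: int = 0) -> RegistryTable:
    """Complete missing cells by Bernoulli draws from the fitted models.

    Columns are completed in temporal order so downstream models may condition
    on already-imputed upstream values; observed cells are never touched.
    Deterministic for a fixed seed.
    """
    out = table.copy()
    by_target = {m.target: m for m in models}
    rng = np.random.default_rng(seed)
    for target in IMPUTATION_ORDER:
        if target not in out.data.columns:
            continue
        missing = out.data[target].isna()
        if not missing.any():
            continue
        model = by_target.get(target)
        if model is None:
            raise ValueError(f"missing cells in {target!r} but no covering model")
        sub = out.data.loc[missing, model.predictors]
        if sub.isna().any().any():
            raise ValueError(
                f"predictors of {target!r} still missing at imputation time")
        p = model.predict(sub)
        draws = (rng.random(int(missing.sum())) < p).astype(np.int8)
        out.data[target] = out.data[target].astype("Int8")
        out.data.loc[missing, target] = draws
        out.data[target] = out.data[target].astype(np.int8)
    out.meta["imputation_seed"] = seed
    return out


def impute(table: RegistryTable, seed: int = 0,
           predictors: dict[str, list[str]] | None = None) -> RegistryTable:
    """Fit models and complete the table in one call (single imputation)."""
    models = fit_imputation_models(table, predictors)
    return impute_stochastic(table, models, seed)
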