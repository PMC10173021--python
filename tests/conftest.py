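"""Shared fixtures: scaled-down synthetic registries and default models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pathmed as pm
from pathmed.published import GROUP_SIZES


def scaled_groups(total: int) -> dict[str, int]:
    """Group sizes with the cohort's SEP mix, scaled to roughly `total`."""
    full = sum(GROUP_SIZES.values())
    return {g: max(1, int(round(n * total / full))) for g, n in GROUP_SIZES.items()}


@pytest.fixture(scope="session")
def default_dag():
    return pm.default_dag()


@pytest.fixture(scope="session")
def small_table():
    """~30k-subject fully observed registry under the default conditions."""
    cfg = pm.default_config(n_per_group=scaled_groups(30000), seed=11)
    return pm.generate_registry(cfg)


@pytest.fixture(scope="session")
def small_config():
    return pm.default_config(n_per_group=scaled_groups(30000), seed=11)


@pytest.fixture(scope="session")
def small_fit(small_table, default_dag):
    return pm.fit_ml(pm.binarize_sep(small_table, "MA_vs_rest"), default_dag)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def counts_table():
    """Subject-level expansion of the printed per-group survival counts."""
    from pathmed.published import EVENT_COUNTS
    rows = []
    for g, n in GROUP_SIZES.items():
        k = EVENT_COUNTS["surv_discharge"][g]
        rows.append(pd.DataFrame({
            "sep_level": g,
            "surv_discharge": np.r_[np.ones(k, dtype=np.int8),
                                    np.zeros(n - k, dtype=np.int8)]}))
    df = pd.concat(rows, ignore_index=True)
    df["sep_level"] = pd.Categorical(df["sep_level"],
                                     categories=list(GROUP_SIZES))
    df["sep_binary"] = (df["sep_level"] == "MA").astype(np.int8)
    cb = {"sep_level": {"type": "categorical", "role": "exposure",
                        "levels": list(GROUP_SIZES)},
          "sep_binary": {"type": "binary", "role": "exposure"},
          "surv_discharge": {"type": "binary", "role": "outcome"}}
    return pm.RegistryTable(df, cb)
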