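"""End-to-end pipeline: simulate -> impute -> screen -> fit -> mediate.

Orchestrates the stages across the four SEP binarization cutoffs and the two
analysis populations (all patients; admitted-only), writing a reproducible
report bundle: descriptive table, odds-ratio tables, mediator screen, SEM fit
JSON with indices, and a mediation decomposition table per scheme, plus a
manifest recording the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dag import DagSpec, admitted_dag, default_dag
from .glm import adjusted_or_table, screen_mediators
from .mediation import mediation_table
from .preprocess import SCHEMES, binarize_sep, impute
from .registry import RegistryTable
from .sem import fit_ml
from .synth import (SyntheticConfig, admitted_config, default_config,
                    generate_registry, inject_missingness)

CONFOUNDERS = ["age", "sex", "diabetes", "hypertension", "metropolitan"]


@dataclass
class RunConfig:
    """One pipeline run: data source, schemes, population, outcome, seed."""

    input_csv: str | None = None          # subject-level CSV; None -> simulate
    codebook: str | None = None
    synthetic: SyntheticConfig | None = None
    schemes: list[str] = field(default_factory=lambda: ["MA_vs_rest"])
    population: str = "all"               # 'all' | 'admitted'
    outcome: str = "surv_discharge"
    seed: int = 0
    out_dir: str | None = None
    with_missingness: bool = True         # only meaningful when simulating
    robust: bool = True

    def validate(self) -> None:
        if self.population not in ("all", "admitted"):
            raise ValueError("population must be 'all' or 'admitted'")
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")


def _load_or_simulate(config: RunConfig) -> RegistryTable:
    if config.input_csv is not None:
        return RegistryTable.from_csv(config.input_csv, config.codebook)
    maker = admitted_config if config.population == "admitted" else default_config
    syn = config.synthetic or maker(seed=config.seed)
    table = generate_registry(syn)
    if config.with_missingness:
        table = inject_missingness(table, syn.missingness, seed=config.seed + 1)
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the bundle and optionally writes it out.

    Identical config + seed produce identical bundles (every random draw is
    seeded deterministically from config.seed).
    """
    config.validate()
    t0 = time.time()
    stage = "load"
    bundle: dict = {"timing": {}, "log": []}
    try:
        table = _load_or_simulate(config)
        bundle["timing"]["load"] = time.time() - t0
        clip = table.meta.get("clip_events", {})
        if any(clip.values()):
            bundle["log"].append(f"linear-probability clipping events: {clip}")

        stage = "impute"
        t = time.time()
        if table.data.isna().any().any():
            table = impute(table, seed=config.seed + 2)
        bundle["timing"]["impute"] = time.time() - t

        stage = "descriptive"
        from .glm import descriptive_table
        bundle["descriptive"] = descriptive_table(table)

        stage = "population"
        if config.population == "admitted":
            sub = RegistryTable(
                table.data[table.data["surv_admission"] == 1].reset_index(drop=True),
                table.codebook, dict(table.meta))
            dag = admitted_dag(config.outcome)
        else:
            sub = table
            dag = default_dag(config.outcome)

        stage = "odds_ratios"
        t = time.time()
        bundle["or_crude"] = adjusted_or_table(sub, config.outcome, confounders=[])
        bundle["or_adjusted"] = adjusted_or_table(sub, config.outcome,
                                                  confounders=CONFOUNDERS)
        bundle["timing"]["odds_ratios"] = time.time() - t

        bundle["schemes"] = {}
        for scheme in config.schemes:
            stage = f"scheme:{scheme}"
            t = time.time()
            binned = binarize_sep(sub, scheme)
            screen = screen_mediators(binned, dag.mediators,
                                      outcome=config.outcome)
            fit = fit_ml(binned, dag, robust=config.robust)
            if not fit.converged:
                bundle["log"].append(f"{scheme}: SEM flagged non-converged")
            med = mediation_table(fit)
            bundle["schemes"][scheme] = {
                "screen": screen, "fit": fit, "mediation": med,
            }
            bundle["timing"][f"scheme:{scheme}"] = time.time() - t
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle["manifest"] = _manifest(config)
    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def sensitivity_grid(config: RunConfig) -> pd.DataFrame:
    """Stacked mediation decomposition across all requested schemes.

    Long format keyed by scheme x pathway, plus per-pathway proportion ranges.
    """
    bundle = run_pipeline(config)
    frames = []
    for scheme, parts in bundle["schemes"].items():
        med = parts["mediation"].copy()
        med.insert(0, "scheme", scheme)
        frames.append(med)
    long = pd.concat(frames, ignore_index=True)
    ranges = (long.dropna(subset=["proportion"])
              .groupby("pathway")["proportion"]
              .agg(prop_min="min", prop_max="max"))
    long = long.merge(ranges, on="pathway", how="left")
    return long


def _manifest(config: RunConfig) -> dict:
    cfg = asdict(config)
    if config.synthetic is not None:
        cfg["synthetic"] = asdict(config.synthetic)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {"seed": config.seed,
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "pathmed_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__}


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["descriptive"].to_csv(out / "descriptive.csv", index=False)
    bundle["or_crude"].to_csv(out / "or_crude.csv", index=False)
    bundle["or_adjusted"].to_csv(out / "or_adjusted.csv", index=False)
    for scheme, parts in bundle["schemes"].items():
        tag = scheme.replace("+", "_")
        parts["screen"].to_csv(out / f"screen_{tag}.csv", index=False)
        parts["mediation"].to_csv(out / f"mediation_{tag}.csv", index=False)
        with open(out / f"sem_fit_{tag}.json", "w") as fh:
            json.dump(parts["fit"].to_dict(), fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump({**bundle["manifest"], "log": bundle["log"],
                   "timing": {k: round(v, 3) for k, v in bundle["timing"].items()}},
                  fh, indent=2)
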