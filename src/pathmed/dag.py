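"""Directed-acyclic-graph specification of the path model.

The analysis model is a recursive observed-variable path model: a binary
low-SEP exposure, a temporally ordered set of binary mediators, and a binary
survival outcome, all on the linear-probability (risk-difference) scale, with
continuous/binary confounders entering every endogenous equation as exogenous
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

CONFOUNDERS = ["age", "sex", "diabetes", "hypertension", "metropolitan"]


@dataclass
class DagSpec:
    """Exposure -> mediators -> outcome DAG plus exogenous covariates.

    `nodes` lists the endogenous variables in temporal order, starting with
    the exposure and ending with the outcome.  `edges` are directed pairs
    among endogenous nodes and must respect that order (recursivity).
    `covariates` are exogenous confounders with edges into every endogenous
    node by default (`covariate_edges` may restrict them).
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    covariates: list[str] = field(default_factory=lambda: list(CONFOUNDERS))
    covariate_edges: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        order = {n: i for i, n in enumerate(self.nodes)}
        self.edges = [tuple(e) for e in self.edges]
        for u, v in self.edges:
            if u not in order or v not in order:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            if order[u] >= order[v]:
                raise ValueError(
                    f"edge ({u}, {v}) violates the declared temporal order")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):  # defensive; order check implies it
            raise ValueError("edge set is cyclic")
        if any(u == self.outcome for u, _ in self.edges):
            raise ValueError("outcome must not have children")
        if any(v == self.exposure for _, v in self.edges):
            raise ValueError("exposure must not have parents among modeled nodes")

    # ------------------------------------------------------------ accessors
    @property
    def exposure(self) -> str:
        return self.nodes[0]

    @property
    def outcome(self) -> str:
        return self.nodes[-1]

    @property
    def mediators(self) -> list[str]:
        return self.nodes[1:-1]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list[str]:
        """Endogenous parents of `node`, in temporal order."""
        ps = {u for u, v in self.edges if v == node}
        return [n for n in self.nodes if n in ps]

    def covariate_parents(self, node: str) -> list[str]:
        if self.covariate_edges is None:
            return list(self.covariates)
        return [c for c, v in self.covariate_edges if v == node]

    def intermediate_confounders(self, mediator: str) -> list[str]:
        """Mediators that confound the `mediator` -> outcome relation.

        An intermediate confounder of M is a variable affected by the
        exposure that affects both M and the outcome.  In a recursive DAG
        where every mediator has a path to the outcome, these are exactly the
        mediator parents of M: excluding them from a pathway set removes
        every exposure -> ... -> M route except the direct exposure -> M edge.
        """
        if mediator not in self.mediators:
            raise ValueError(f"{mediator!r} is not a mediator of this DAG")
        return [p for p in self.parents(mediator) if p in self.mediators]

    # ------------------------------------------------------------------ io
    def to_yaml(self, path: str | Path) -> None:
        payload = {"nodes": self.nodes,
                   "edges": [list(e) for e in self.edges],
                   "covariates": self.covariates}
        if self.covariate_edges is not None:
            payload["covariate_edges"] = [list(e) for e in self.covariate_edges]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DagSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cov_edges = payload.get("covariate_edges")
        return cls(nodes=payload["nodes"],
                   edges=[tuple(e) for e in payload["edges"]],
                   covariates=payload.get("covariates", list(CONFOUNDERS)),
                   covariate_edges=[tuple(e) for e in cov_edges] if cov_edges else None)


def default_dag(outcome: str = "surv_discharge") -> DagSpec:
    """Full-population path model: SEP -> {witnessed, bystander CPR, initial
    rhythm, ED level} -> survival.

    Witnessed status feeds bystander CPR and initial rhythm; bystander CPR
    feeds initial rhythm.  ED level has no mediator parents (its assignment is
    driven by region and SEP, not by the arrest circumstances here).
    """
    nodes = ["sep_binary", "witnessed", "bystander_cpr", "shockable",
             "ed_level12", outcome]
    edges = [
        ("sep_binary", "witnessed"),
        ("sep_binary", "bystander_cpr"),
        ("sep_binary", "shockable"),
        ("sep_binary", "ed_level12"),
        ("sep_binary", outcome),
        ("witnessed", "bystander_cpr"),
        ("witnessed", "shockable"),
        ("witnessed", outcome),
        ("bystander_cpr", "shockable"),
        ("bystander_cpr", outcome),
        ("shockable", outcome),
        ("ed_level12", outcome),
    ]
    return DagSpec(nodes=nodes, edges=edges)


def admitted_dag(outcome: str = "surv_discharge") -> DagSpec:
    """Admitted-population path model: adds coronary angiography (CAG,
    downstream of initial rhythm and ED level) and targeted temperature
    management (TTM, downstream of ED level)."""
    base = default_dag(outcome)
    nodes = base.nodes[:-1] + ["cag", "ttm", outcome]
    edges = [e for e in base.edges] + [
        ("sep_binary", "cag"),
        ("sep_binary", "ttm"),
        ("shockable", "cag"),
        ("ed_level12", "cag"),
        ("ed_level12", "ttm"),
        ("cag", outcome),
        ("ttm", outcome),
    ]
    return DagSpec(nodes=nodes, edges=edges)
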