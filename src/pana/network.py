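"""Pathway-network assembly and export.

Accuracy-filtered association rules become edges of a pathway-profile
network. Nodes are pathway profiles (``pathwayID#componentIndex``), edges
carry the rule class, accuracy and profile correlation; direct edges are
annotated blue and opposite edges red for viewer parity. Optionally,
mutual same-class rule pairs are merged into a single undirected edge
keeping the higher accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .compression import ProfileSet
from .drivers import DrivingGeneReport
from .rules import AssociationRule

__all__ = [
    "PathwayNetwork",
    "build_network",
    "same_sep_fraction",
    "write_graphml",
    "read_graphml",
    "write_sif",
]

EDGE_COLORS = {"direct": "blue", "opposite": "red"}


@dataclass
class PathwayNetwork:
    """A pathway-profile graph plus the parameters that produced it."""

    graph: nx.Graph | nx.DiGraph
    params: dict = field(default_factory=dict)

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_by_class(self, rule_class: str | None = None):
        for u, v, data in self.graph.edges(data=True):
            if rule_class is None or data.get("rule_class") == rule_class:
                yield u, v, data


def build_network(rules: list[AssociationRule], profile_set: ProfileSet,
                  drivers: dict[str, DrivingGeneReport] | None = None,
                  dedupe: bool = False,
                  params: dict | None = None) -> PathwayNetwork:
    """Assemble a network from accuracy-filtered rules.

    With ``dedupe`` mutual edges (l->j and j->l of the same class) merge
    into one undirected edge keeping the maximum accuracy; otherwise the
    graph is directed (source -> target). Every profile of the profile set
    becomes a node; a rule referencing an unknown profile is an error.
    """
    known = set(profile_set.profile_ids)
    for r in rules:
        if r.source not in known or r.target not in known:
            raise ValueError(f"rule {r.source}->{r.target} references an "
                             "unknown profile")
    g: nx.Graph | nx.DiGraph = nx.Graph() if dedupe else nx.DiGraph()
    for p in profile_set.profiles:
        attrs = {"pathway": p.pathway_id, "component": p.component_index}
        if drivers and p.profile_id in drivers:
            rep = drivers[p.profile_id]
            attrs["driving_genes"] = ",".join(gn for gn, _ in rep.driving_genes)
            attrs["driver_flag"] = rep.flag
        g.add_node(p.profile_id, **attrs)
    for r in rules:
        attrs = {
            "rule_class": r.rule_class,
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "correlation": r.correlation,
            "threshold": r.threshold,
            "color": EDGE_COLORS[r.rule_class],
        }
        if dedupe and g.has_edge(r.source, r.target):
            old = g.edges[r.source, r.target]
            if old["rule_class"] == r.rule_class and old["accuracy"] >= r.accuracy:
                continue
        g.add_edge(r.source, r.target, **attrs)
    return PathwayNetwork(g, dict(params or {}))


def same_sep_fraction(network: PathwayNetwork,
                      truth: dict[str, tuple[int, float, int]],
                      rule_class: str | None = None) -> float:
    """Fraction of edges joining pathways with the same planted SEP.

    ``truth`` maps pathway id -> (SEP id, inner correlation, size) as
    produced by the simulation module. Restrict to one rule class with
    ``rule_class``; raises on an empty edge set or a pathway missing from
    the truth table.
    """
    same = total = 0
    for u, v, _ in network.edges_by_class(rule_class):
        pu = network.graph.nodes[u].get("pathway", u.rsplit("#", 1)[0])
        pv = network.graph.nodes[v].get("pathway", v.rsplit("#", 1)[0])
        for p in (pu, pv):
            if p not in truth:
                raise KeyError(f"pathway {p} missing from truth table")
        total += 1
        if truth[pu][0] == truth[pv][0]:
            same += 1
    if total == 0:
        raise ValueError("network has no edges of the requested class")
    return same / total


def write_graphml(network: PathwayNetwork, path) -> None:
    g = network.graph.copy()
    for k, v in network.params.items():
        g.graph[f"param_{k}"] = str(v)
    nx.write_graphml(g, path)


def read_graphml(path) -> PathwayNetwork:
    g = nx.read_graphml(path)
    params = {k[len("param_"):]: v for k, v in g.graph.items()
              if k.startswith("param_")}
    for k in list(g.graph):
        if k.startswith("param_"):
            del g.graph[k]
    return PathwayNetwork(g, params)


def write_sif(network: PathwayNetwork, path) -> None:
    """Minimal SIF export: source TAB rule-class TAB target."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in network.graph.edges(data=True):
            fh.write(f"{u}\t{data.get('rule_class', 'assoc')}\t{v}\n")
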