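"""Construction of drug-target, drug-drug and adverse-effect networks.

All constructed graphs are simple undirected bipartite graphs: no self-loops,
no parallel edges, every edge joins nodes of different roles. Isolated drug
nodes are deliberately preserved — a drug with no recorded target is one of
the analysis' key observables — while targets with no interaction never enter
a network.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .ingest import AdverseEffectAnnotation, DrugRecord, Interaction, TargetRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "DrugDrugNetwork",
    "build_drug_target_network",
    "derive_shared_target_network",
    "build_adverse_effect_network",
    "write_edge_list",
    "write_node_table",
    "read_network",
]

ROLES = ("drug", "target", "effect")


class BipartiteNetwork:
    """Simple undirected graph with role-typed nodes (drug | target | effect)."""

    def __init__(self, label: str = ""):
        self.label = label
        self.graph = nx.Graph()

    # -- construction ------------------------------------------------------
    def add_node(self, node_id: str, role: str) -> None:
        if role not in ROLES:
            raise ValueError(f"unknown node role {role!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["role"] != role:
            raise ValueError(
                f"node {node_id!r} already present with role {existing['role']!r}, got {role!r}"
            )
        self.graph.add_node(node_id, role=role)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        for n in (u, v):
            if n not in self.graph:
                raise KeyError(f"node {n!r} must be added with a role before an edge")
        if self.graph.nodes[u]["role"] == self.graph.nodes[v]["role"]:
            raise ValueError(
                f"edge {u!r}-{v!r} joins two {self.graph.nodes[u]['role']!r} nodes"
            )
        self.graph.add_edge(u, v)

    # -- queries -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == role}

    def role_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["role"]

    def degree(self, node_id: str) -> int:
        return self.graph.degree[node_id]

    def neighbors(self, node_id: str) -> set[str]:
        return set(self.graph.neighbors(node_id))

    def targets_of(self, drug_id: str) -> set[str]:
        return {n for n in self.graph.neighbors(drug_id) if self.role_of(n) == "target"}

    def is_bipartite_by_role(self) -> bool:
        """Role assignment is a valid two-coloring (holds by construction)."""
        return all(
            self.graph.nodes[u]["role"] != self.graph.nodes[v]["role"]
            for u, v in self.graph.edges
        )

    def subnetwork(self, nodes: Iterable[str], label: str | None = None) -> "BipartiteNetwork":
        sub = BipartiteNetwork(label if label is not None else self.label)
        sub.graph = self.graph.subgraph(nodes).copy()
        return sub

    def __repr__(self) -> str:
        return f"BipartiteNetwork({self.label!r}, {self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class DrugDrugNetwork:
    """Withdrawn-approved drug pairs linked by at least one shared target.

    An edge (w, a) exists iff the withdrawn drug w and the approved drug a
    interact with at least one common target; the shared target set is kept
    on the edge. Drugs with no cross-partition partner do not appear.
    """

    withdrawn_nodes: set[str] = field(default_factory=set)
    approved_nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def approved_neighbors(self, withdrawn_id: str) -> set[str]:
        return {a for (w, a) in self.edges if w == withdrawn_id}

    def withdrawn_neighbors(self, approved_id: str) -> set[str]:
        return {w for (w, a) in self.edges if a == approved_id}

    def shared_targets(self, withdrawn_id: str, approved_id: str) -> frozenset[str]:
        return self.edges.get((withdrawn_id, approved_id), frozenset())


def build_drug_target_network(
    drugs: Sequence[DrugRecord],
    targets: Sequence[TargetRecord],
    interactions: Sequence[Interaction],
    label: str = "",
    *,
    strict: bool = False,
) -> BipartiteNetwork:
    """Build a drug-target bipartite network.

    Every listed drug becomes a node even with zero interactions (isolated
    drug nodes are preserved); target nodes are created only when an
    interaction references them, so targets with no drug never appear.
    Duplicate interactions collapse to one edge. An interaction naming an
    unlisted drug is an error in strict mode, otherwise skipped and logged;
    an unlisted target is an error in strict mode, otherwise created on the
    fly.
    """
    net = BipartiteNetwork(label)
    drug_ids = {d.drug_id for d in drugs}
    target_ids = {t.target_id for t in targets}
    for d in drugs:
        net.add_node(d.drug_id, "drug")
    n_skipped = 0
    for it in interactions:
        if it.drug_id not in drug_ids:
            if strict:
                raise ValueError(f"interaction references unlisted drug {it.drug_id!r}")
            n_skipped += 1
            logger.info("%s: skipped interaction with unlisted drug %r", label, it.drug_id)
            continue
        if it.target_id not in target_ids:
            if strict:
                raise ValueError(f"interaction references unlisted target {it.target_id!r}")
            logger.info("%s: target %r created from interaction", label, it.target_id)
        net.add_node(it.target_id, "target")
        net.add_edge(it.drug_id, it.target_id)
    if n_skipped:
        logger.info("%s: %d interactions skipped (unlisted drug)", label, n_skipped)
    return net


def derive_shared_target_network(
    withdrawn_net: BipartiteNetwork, approved_net: BipartiteNetwork
) -> DrugDrugNetwork:
    """Link withdrawn and approved drugs that hit at least one common target.

    Matching is by target_id only. A drug id present on both sides would
    self-pair; such pairs are dropped and logged. Any number of shared
    targets still yields a single edge (simple-graph contract), with the
    full intersection stored on it.
    """
    # index: target -> drugs touching it, per network
    by_target_w: dict[str, set[str]] = {}
    for w in withdrawn_net.nodes_with_role("drug"):
        for t in withdrawn_net.targets_of(w):
            by_target_w.setdefault(t, set()).add(w)
    ddnet = DrugDrugNetwork()
    shared: dict[tuple[str, str], set[str]] = {}
    for a in approved_net.nodes_with_role("drug"):
        for t in approved_net.targets_of(a):
            for w in by_target_w.get(t, ()):
                if w == a:
                    logger.info("drug %r appears in both networks; self-pair dropped", w)
                    continue
                shared.setdefault((w, a), set()).add(t)
    for (w, a), ts in shared.items():
        ddnet.withdrawn_nodes.add(w)
        ddnet.approved_nodes.add(a)
        ddnet.edges[(w, a)] = frozenset(ts)
    return ddnet


def build_adverse_effect_network(
    annotations: Sequence[AdverseEffectAnnotation], label: str = "adverse effects"
) -> BipartiteNetwork:
    """Bipartite network of withdrawn drugs vs. adverse-effect categories."""
    net = BipartiteNetwork(label)
    for ann in annotations:
        net.add_node(ann.drug_id, "drug")
        net.add_node(ann.effect, "effect")
        net.add_edge(ann.drug_id, ann.effect)
    return net


def write_edge_list(net: BipartiteNetwork, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target"])
        for u, v in sorted(net.graph.edges):
            writer.writerow([u, v])


def write_node_table(net: BipartiteNetwork, path: str | Path) -> None:
    """Node attribute table (id, role) consumable by standard graph viewers."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_id", "role"])
        for n in sorted(net.graph.nodes):
            writer.writerow([n, net.role_of(n)])


def read_network(edge_path: str | Path, node_path: str | Path, label: str = "") -> BipartiteNetwork:
    net = BipartiteNetwork(label)
    with Path(node_path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            net.add_node(row["node_id"], row["role"])
    with Path(edge_path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            net.add_edge(row["source"], row["target"])
    return net
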