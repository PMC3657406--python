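"""Connected-core extraction, vertex centralities, and target-set comparison.

Centralities follow the conventions of classic centrality tools for
undirected connected graphs:

* degree          — raw neighbor count;
* eccentricity    — longest shortest path from the node, in hops;
* closeness       — 1 / (sum of distances to all other nodes); an averaged
                    (normalized) variant (N-1)/sum is emitted alongside;
* betweenness     — unnormalized shortest-path betweenness over unordered
                    pairs, tied paths credited fractionally, endpoints
                    excluded (every leaf scores 0);
* eigenvector     — principal adjacency eigenvector, scaled to max 1,
                    computed by power iteration on A + I. The identity shift
                    is required for bipartite graphs, whose adjacency
                    spectrum is symmetric (+/- lambda_max), where plain
                    power iteration oscillates; the shift leaves the
                    eigenvectors unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TargetComparison",
    "extract_connected_core",
    "compute_centralities",
    "eigenvector_centrality",
    "compare_target_sets",
]

EIGENVECTOR_TOL = 1e-10
EIGENVECTOR_MAX_ITER = 10_000


def extract_connected_core(net: BipartiteNetwork) -> BipartiteNetwork:
    """Largest connected component as a new network (idempotent).

    Ties between equally large components are broken toward the component
    containing the lexicographically smallest node id, so extraction is
    deterministic. Retention counts are logged. An empty graph yields an
    empty core.
    """
    components = list(nx.connected_components(net.graph))
    if not components:
        return BipartiteNetwork(net.label)
    biggest = max(len(c) for c in components)
    core_nodes = min(
        (c for c in components if len(c) == biggest), key=lambda c: min(c)
    )
    core = net.subnetwork(core_nodes)
    n_drugs = len(core.nodes_with_role("drug"))
    logger.info(
        "%s: connected core retains %d of %d nodes (%d drug nodes)",
        net.label,
        core.n_nodes,
        net.n_nodes,
        n_drugs,
    )
    return core


def eigenvector_centrality(
    graph: nx.Graph,
    tol: float = EIGENVECTOR_TOL,
    max_iter: int = EIGENVECTOR_MAX_ITER,
) -> dict[str, float]:
    """Principal-eigenvector weights scaled to max 1, by power iteration.

    Deterministic uniform start vector; iterates x <- (A + I) x until the
    max-norm change of the normalized vector is below tol.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    a = nx.to_numpy_array(graph, nodelist=nodes)
    np.fill_diagonal(a, a.diagonal() + 1.0)  # shift: A + I
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = a @ x
        x_new /= x_new.max()
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(f"eigenvector power iteration did not converge in {max_iter} steps")
    return {node: float(val) for node, val in zip(nodes, x)}


def compute_centralities(core: BipartiteNetwork) -> pd.DataFrame:
    """Per-node centrality table for a connected graph of at least 2 nodes.

    Returns a DataFrame indexed by node id with columns role, degree,
    eccentricity, closeness, closeness_normalized, betweenness, eigenvector.
    Raises on disconnected input: run extract_connected_core first.
    """
    g = core.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("centralities need a connected graph with at least 2 nodes")
    if not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected; apply extract_connected_core before computing centralities"
        )
    ecc = nx.eccentricity(g)
    dist_sum = {
        node: sum(nx.single_source_shortest_path_length(g, node).values()) for node in g.nodes
    }
    betweenness = nx.betweenness_centrality(g, normalized=False)
    eigen = eigenvector_centrality(g)
    rows = {
        node: {
            "role": core.role_of(node),
            "degree": g.degree[node],
            "eccentricity": ecc[node],
            "closeness": 1.0 / dist_sum[node],
            "closeness_normalized": (n - 1) / dist_sum[node],
            "betweenness": betweenness[node],
            "eigenvector": eigen[node],
        }
        for node in g.nodes
    }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "node_id"
    return table


@dataclass(frozen=True)
class TargetComparison:
    """Three-way partition of the target ids of two connected cores.

    ``common_degrees`` carries, for each shared target, its degree in both
    cores — high in both flags a crowded (and historically risky) target,
    low in both a deserted one. ``bottlenecks_a`` / ``bottlenecks_b`` are
    the common targets that are articulation points of the respective core:
    removing one disconnects the graph.
    """

    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    common_degrees: dict[str, tuple[int, int]]
    bottlenecks_a: frozenset[str]
    bottlenecks_b: frozenset[str]


def compare_target_sets(core_a: BipartiteNetwork, core_b: BipartiteNetwork) -> TargetComparison:
    """Partition targets of two drug-target cores into common/exclusive sets."""
    ta = core_a.nodes_with_role("target")
    tb = core_b.nodes_with_role("target")
    common = frozenset(ta & tb)
    art_a = set(nx.articulation_points(core_a.graph)) if core_a.n_nodes else set()
    art_b = set(nx.articulation_points(core_b.graph)) if core_b.n_nodes else set()
    return TargetComparison(
        common=common,
        only_a=frozenset(ta - tb),
        only_b=frozenset(tb - ta),
        common_degrees={t: (core_a.degree(t), core_b.degree(t)) for t in sorted(common)},
        bottlenecks_a=frozenset(common & art_a),
        bottlenecks_b=frozenset(common & art_b),
    )
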