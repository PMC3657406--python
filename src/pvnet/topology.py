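"""Whole-network topology metrics and drug-node degree distributions.

Conventions for disconnected graphs (drug-target networks routinely contain
isolated drug nodes, so every distance-based metric must be defined without
a connectedness assumption):

* diameter = maximum finite shortest-path distance;
* characteristic path length = mean distance over ordered node pairs in the
  same component (finite distances only);
* shortest_paths = count of ordered same-component pairs, i.e.
  sum over components of n_i * (n_i - 1);
* radius = minimum within-component eccentricity over non-isolated nodes,
  so a network whose components are stars around hubs has radius 1 no
  matter how many isolated nodes it carries.

Degree-derived panel entries:

* density           = 2E / (N (N-1))
* avg_neighbors     = 2E / N
* heterogeneity     = sd(degree) / mean(degree)   (population sd)
* centralization    = (N / (N-2)) * (max_degree/(N-1) - density)
                      (Freeman degree centralization; 1.0 for a star, 0 for
                      any regular graph; reported as 0 with a warning when
                      N < 3, where the formula is undefined)
* clustering        = mean over ALL nodes of the local triangle fraction,
                      nodes of degree < 2 contributing 0
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from ._util import round_half_up
from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "DegreeDistribution",
    "DEGREE_BIN_LABELS",
    "summarize_topology",
    "degree_distribution",
    "percent_isolated",
    "density_from_mean_degree",
]

# right-closed degree bins used for drug-node degree profiles
DEGREE_BIN_EDGES = (2, 4, 6, 20)
DEGREE_BIN_LABELS = ("<=2", "(2,4]", "(4,6]", "(6,20]", ">20")


@dataclass(frozen=True)
class TopologySummary:
    """The whole-network metric panel for one network."""

    label: str
    clustering_coefficient: float
    connected_components: int
    diameter: int
    radius: int
    centralization: float
    shortest_paths: int
    characteristic_path_length: float
    avg_neighbors: float
    n_nodes: int
    n_drug_nodes: int
    density: float
    heterogeneity: float
    isolated_nodes: int
    isolated_percent: float  # percent of drug nodes
    self_loops: int
    multiedge_pairs: int

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "label": self.label,
            "clustering_coefficient": self.clustering_coefficient,
            "connected_components": self.connected_components,
            "network_diameter": self.diameter,
            "network_radius": self.radius,
            "network_centralization": self.centralization,
            "shortest_paths": self.shortest_paths,
            "characteristic_path_length": self.characteristic_path_length,
            "avg_number_of_neighbors": self.avg_neighbors,
            "number_of_nodes": self.n_nodes,
            "number_of_drug_nodes": self.n_drug_nodes,
            "network_density": self.density,
            "network_heterogeneity": self.heterogeneity,
            "isolated_nodes": self.isolated_nodes,
            "isolated_percent": self.isolated_percent,
            "number_of_self_loops": self.self_loops,
            "multiedge_node_pairs": self.multiedge_pairs,
        }


@dataclass(frozen=True)
class DegreeDistribution:
    """Binned degree profile of one node role (drug nodes in practice)."""

    role: str
    n_drugs: int
    mean_degree: float
    sd_degree: float  # sample sd (ddof=1); 0 when n < 2
    bins: Mapping[str, float]  # label -> percent of role nodes

    def mean_sd_text(self, ndigits: int = 3) -> str:
        return f"{round_half_up(self.mean_degree, ndigits)} ± {round_half_up(self.sd_degree, ndigits)}"


def _distance_stats(graph: nx.Graph) -> tuple[int, int, float, int]:
    """(diameter, shortest_paths, characteristic_path_length, radius).

    One BFS per node; only finite (same-component) distances contribute.
    Radius is the minimum eccentricity over non-isolated nodes; all-isolated
    or empty graphs report 0 for every distance metric.
    """
    diameter = 0
    n_pairs = 0
    total = 0
    radius: int | None = None
    for node in graph.nodes:
        if graph.degree[node] == 0:
            continue
        lengths = nx.single_source_shortest_path_length(graph, node)
        ecc = max(lengths.values())
        diameter = max(diameter, ecc)
        radius = ecc if radius is None else min(radius, ecc)
        n_pairs += len(lengths) - 1  # ordered pairs from this source
        total += sum(lengths.values())
    cpl = total / n_pairs if n_pairs else 0.0
    return diameter, n_pairs, cpl, radius if radius is not None else 0


def summarize_topology(net: BipartiteNetwork) -> TopologySummary:
    """Compute the full metric panel; disconnected and empty graphs allowed."""
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)

    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_neighbors = 2 * e / n if n else 0.0

    if n < 3:
        if n:
            warnings.warn("centralization undefined for N < 3; reported as 0", stacklevel=2)
        centralization = 0.0
    else:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)

    mean_deg = float(degrees.mean()) if n else 0.0
    sd_deg = float(degrees.std()) if n else 0.0  # population sd
    heterogeneity = sd_deg / mean_deg if mean_deg > 0 else 0.0

    clustering = nx.average_clustering(g) if n else 0.0
    components = nx.number_connected_components(g)
    diameter, n_pairs, cpl, radius = _distance_stats(g)

    drug_nodes = net.nodes_with_role("drug")
    isolated = [node for node in g.nodes if g.degree[node] == 0]
    n_iso_drugs = sum(1 for node in isolated if node in drug_nodes)
    iso_pct = round_half_up(100 * n_iso_drugs / len(drug_nodes), 2) if drug_nodes else 0.0

    return TopologySummary(
        label=net.label,
        clustering_coefficient=clustering,
        connected_components=components,
        diameter=diameter,
        radius=radius,
        centralization=centralization,
        shortest_paths=n_pairs,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        n_nodes=n,
        n_drug_nodes=len(drug_nodes),
        density=density,
        heterogeneity=heterogeneity,
        isolated_nodes=len(isolated),
        isolated_percent=iso_pct,
        self_loops=nx.number_of_selfloops(g),
        multiedge_pairs=0,  # nx.Graph cannot hold parallel edges
    )


def degree_distribution(net: BipartiteNetwork, role: str = "drug") -> DegreeDistribution:
    """Bin the degrees of one node role into the five standard bins.

    Bins are closed on the right: degree 2 falls in <=2, degree 4 in (2,4],
    and so on. Percentages are of all role nodes (isolated ones included)
    and rounded half-up to 2 decimals.
    """
    nodes = sorted(net.nodes_with_role(role))
    if not nodes:
        return DegreeDistribution(
            role=role,
            n_drugs=0,
            mean_degree=0.0,
            sd_degree=0.0,
            bins={lab: 0.0 for lab in DEGREE_BIN_LABELS},
        )
    degs = np.array([net.degree(n) for n in nodes], dtype=float)
    edges = (-np.inf,) + DEGREE_BIN_EDGES + (np.inf,)
    counts = [
        int(np.sum((degs > lo) & (degs <= hi))) for lo, hi in zip(edges[:-1], edges[1:])
    ]
    bins = {
        lab: round_half_up(100 * c / len(nodes), 2) for lab, c in zip(DEGREE_BIN_LABELS, counts)
    }
    return DegreeDistribution(
        role=role,
        n_drugs=len(nodes),
        mean_degree=float(degs.mean()),
        sd_degree=float(degs.std(ddof=1)) if len(nodes) > 1 else 0.0,
        bins=bins,
    )


def percent_isolated(net: BipartiteNetwork, role: str = "drug") -> tuple[int, float]:
    """Count and percentage (2 decimals, half-up) of degree-0 nodes of a role."""
    nodes = net.nodes_with_role(role)
    if not nodes:
        return 0, 0.0
    count = sum(1 for n in nodes if net.degree(n) == 0)
    return count, round_half_up(100 * count / len(nodes), 2)


def density_from_mean_degree(n_nodes: int, avg_neighbors: float) -> float:
    """Density of a simple graph from its size and mean degree.

    For every simple graph density = avg_neighbors / (N - 1); this identity
    lets the density panel entry be cross-checked (or recovered from a
    printed node count and mean-neighbor value).
    """
    if n_nodes < 2:
        return 0.0
    return avg_neighbors / (n_nodes - 1)
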