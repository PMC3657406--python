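"""Shared fixtures: tiny hand-built networks and a scaled-down synthetic study."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from pvnet.network import BipartiteNetwork
from pvnet.synthetic_data import GeneratorConfig, generate_study


def net_from_edges(edges, isolated_drugs=(), label="test"):
    """BipartiteNetwork from (drug, target) pairs plus isolated drug nodes."""
    net = BipartiteNetwork(label)
    for d in isolated_drugs:
        net.add_node(d, "drug")
    for d, t in edges:
        net.add_node(d, "drug")
        net.add_node(t, "target")
        net.add_edge(d, t)
    return net


def net_from_nx(graph: nx.Graph, label="test") -> BipartiteNetwork:
    """Wrap an arbitrary bipartite nx graph, roles assigned by 2-coloring."""
    color = nx.bipartite.color(graph) if graph.number_of_edges() else {n: 0 for n in graph}
    net = BipartiteNetwork(label)
    for n in graph.nodes:
        net.add_node(str(n), "drug" if color.get(n, 0) == 0 else "target")
    for u, v in graph.edges:
        net.add_edge(str(u), str(v))
    return net


def random_bipartite(n_top: int, n_bottom: int, n_edges: int, seed: int) -> BipartiteNetwork:
    g = nx.bipartite.gnmk_random_graph(n_top, n_bottom, n_edges, seed=seed)
    return net_from_nx(g)


@pytest.fixture
def star_net():
    """K_{1,4}: one hub target, four drugs."""
    return net_from_edges([(f"d{i}", "t0") for i in range(4)])


@pytest.fixture
def path3_net():
    """P3: d1 - t1 - d2."""
    return net_from_edges([("d1", "t1"), ("d2", "t1")])


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A fast, fully planted study configuration for tests."""
    defaults = dict(
        n_approved=120,
        n_withdrawn=30,
        n_targets_approved=60,
        n_targets_withdrawn=30,
        overlap_targets=10,
        n_natural_products=40,
        n_bits=512,
        n_planted_probes=2,
        probe_neighbor_count=12,
        planted_flags_per_probe=2,
        n_np_approved_only=10,
        n_np_withdrawn_only=1,
        n_np_both=3,
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20130429)
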