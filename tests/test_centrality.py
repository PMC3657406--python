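"""Connected-core extraction and vertex centralities against brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import net_from_edges, net_from_nx
from pvnet.centrality import (
    compare_target_sets,
    compute_centralities,
    eigenvector_centrality,
    extract_connected_core,
)
from pvnet.topology import summarize_topology


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Betweenness by explicit enumeration of ALL minimal paths.

    For every unordered pair, enumerates every simple path of minimal length
    by depth-first search (no shortest-path library machinery) and credits
    interior nodes fractionally.
    """
    nodes = list(g.nodes)
    bt = {v: 0.0 for v in nodes}

    def all_paths(s, t):
        paths = []

        def walk(node, seen, path):
            if node == t:
                paths.append(list(path))
                return
            for nb in g[node]:
                if nb not in seen:
                    walk(nb, seen | {nb}, path + [nb])

        walk(s, {s}, [s])
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for p in shortest:
            for v in p[1:-1]:
                bt[v] += 1.0 / len(shortest)
    return bt


def connected_bipartite(seed: int, max_nodes: int = 14) -> nx.Graph:
    rng = np.random.default_rng(seed)
    while True:
        g = nx.bipartite.gnmk_random_graph(
            int(rng.integers(2, max_nodes // 2)),
            int(rng.integers(2, max_nodes // 2)),
            int(rng.integers(4, 20)),
            seed=int(rng.integers(0, 2**31)),
        )
        if g.number_of_nodes() and nx.is_connected(g):
            return g


class TestExtractConnectedCore:
    def test_largest_component_wins(self):
        net = net_from_edges(
            [("d1", "t1"), ("d2", "t1"), ("d3", "t1"), ("d4", "t2"), ("d5", "t2"), ("d6", "t3")]
        )
        core = extract_connected_core(net)
        assert set(core.graph.nodes) == {"d1", "d2", "d3", "t1"}

    def test_identity_when_connected(self, star_net):
        core = extract_connected_core(star_net)
        assert set(core.graph.nodes) == set(star_net.graph.nodes)

    def test_tie_broken_by_smallest_node_id(self):
        net = net_from_edges([("a1", "z1"), ("b1", "z2")])
        core = extract_connected_core(net)
        assert set(core.graph.nodes) == {"a1", "z1"}

    def test_idempotent(self):
        net = net_from_edges([("d1", "t1"), ("d2", "t2")], isolated_drugs=["d9"])
        once = extract_connected_core(net)
        twice = extract_connected_core(once)
        assert set(once.graph.nodes) == set(twice.graph.nodes)

    def test_empty_graph_empty_core(self):
        from pvnet.network import BipartiteNetwork

        core = extract_connected_core(BipartiteNetwork("empty"))
        assert core.n_nodes == 0


class TestComputeCentralities:
    def test_path3_center(self, path3_net):
        table = compute_centralities(path3_net)
        assert table.loc["t1", "betweenness"] == pytest.approx(1.0)
        assert table.loc["t1", "closeness"] == pytest.approx(0.5)
        assert table.loc["d1", "betweenness"] == 0.0  # leaf

    def test_star_hub_and_leaves(self, star_net):
        table = compute_centralities(star_net)
        assert table.loc["t0", "closeness"] == pytest.approx(1 / 4)
        assert table.loc["t0", "eccentricity"] == 1
        assert (table.loc[[f"d{i}" for i in range(4)], "eccentricity"] == 2).all()
        assert table.loc["t0", "eigenvector"] == pytest.approx(1.0)

    def test_vertex_transitive_graph_uniform(self):
        table = compute_centralities(net_from_nx(nx.cycle_graph(8)))
        for col in ("degree", "eccentricity", "closeness", "betweenness", "eigenvector"):
            assert table[col].nunique() == 1

    def test_disconnected_input_rejected(self):
        net = net_from_edges([("d1", "t1"), ("d2", "t2")])
        with pytest.raises(ValueError, match="extract_connected_core"):
            compute_centralities(net)

    @pytest.mark.parametrize("seed", range(3))
    def test_betweenness_matches_path_enumeration_oracle(self, seed):
        g = connected_bipartite(seed)
        net = net_from_nx(g)
        table = compute_centralities(net)
        oracle = brute_force_betweenness(net.graph)
        for node, expected in oracle.items():
            assert table.loc[str(node), "betweenness"] == pytest.approx(expected)

    def test_betweenness_tree_identity(self):
        # on trees: sum of betweenness = (unordered connected pairs) * (CPL - 1)
        tree = nx.random_labeled_tree(12, seed=42)
        net = net_from_nx(tree)
        table = compute_centralities(net)
        s = summarize_topology(net)
        pairs = s.shortest_paths / 2
        assert table["betweenness"].sum() == pytest.approx(
            pairs * (s.characteristic_path_length - 1)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_eigenvector_matches_dense_eigensolver(self, seed):
        g = connected_bipartite(seed)
        nodes = list(g.nodes)
        vals, vecs = np.linalg.eigh(nx.to_numpy_array(g, nodelist=nodes))
        lead = np.abs(vecs[:, np.argmax(vals)])
        lead /= lead.max()
        computed = eigenvector_centrality(g)
        for node, expected in zip(nodes, lead):
            assert computed[node] == pytest.approx(expected, abs=1e-6)

    def test_eigenvector_isomorphism_invariant(self):
        g = connected_bipartite(11)
        relabeled = nx.relabel_nodes(g, {n: f"x{n}" for n in g.nodes})
        e1 = eigenvector_centrality(g)
        e2 = eigenvector_centrality(relabeled)
        for n in g.nodes:
            assert e1[n] == pytest.approx(e2[f"x{n}"], abs=1e-8)

    def test_closeness_positive_and_eigenvector_in_unit_interval(self, star_net):
        table = compute_centralities(star_net)
        assert (table["closeness"] > 0).all()
        assert ((table["eigenvector"] > 0) & (table["eigenvector"] <= 1)).all()


class TestCompareTargetSets:
    def test_three_way_partition(self):
        core_a = net_from_edges([("d1", "t1"), ("d1", "t2")])
        core_b = net_from_edges([("d2", "t2"), ("d2", "t3")])
        cmp = compare_target_sets(core_a, core_b)
        assert cmp.common == {"t2"}
        assert cmp.only_a == {"t1"} and cmp.only_b == {"t3"}
        assert cmp.common_degrees["t2"] == (1, 1)

    def test_identical_and_disjoint(self):
        core = net_from_edges([("d1", "t1")])
        same = compare_target_sets(core, core)
        assert same.only_a == frozenset() and same.only_b == frozenset()
        other = net_from_edges([("d2", "t9")])
        assert compare_target_sets(core, other).common == frozenset()

    def test_sets_disjoint_and_cover_union(self):
        core_a = net_from_edges([("d1", "t1"), ("d1", "t2"), ("d2", "t3")])
        core_b = net_from_edges([("d3", "t2"), ("d3", "t4")])
        cmp = compare_target_sets(core_a, core_b)
        assert not (cmp.common & cmp.only_a or cmp.common & cmp.only_b or cmp.only_a & cmp.only_b)
        assert cmp.common | cmp.only_a | cmp.only_b == {"t1", "t2", "t3", "t4"}

    def test_bottleneck_targets_are_articulation_points(self):
        # t1 is the cut vertex of a path d1-t1-d2 in both cores
        core_a = net_from_edges([("d1", "t1"), ("d2", "t1")])
        core_b = net_from_edges([("d3", "t1"), ("d4", "t1")])
        cmp = compare_target_sets(core_a, core_b)
        assert cmp.bottlenecks_a == {"t1"} and cmp.bottlenecks_b == {"t1"}
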