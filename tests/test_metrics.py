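"""Graph statistics against brute-force path/triangle enumeration."""

import numpy as np
import pytest

from oracles import brute_betweenness, brute_clustering, brute_pearson, random_adj

from conftest import build_network, net_from_adj

from netpharm.metrics import (
    betweenness,
    betweenness_all,
    clustering_coefficient,
    degree_assortativity,
    degree_distribution,
    network_summary,
)


class TestClustering:
    def test_triangle_is_fully_clustered(self, triangle):
        assert clustering_coefficient(triangle, "A") == 1.0

    def test_path_center_unclustered(self, path4):
        assert clustering_coefficient(path4, "B") == 0.0

    def test_low_degree_returns_zero(self, path4):
        assert clustering_coefficient(path4, "A") == 0.0

    def test_partial_neighborhood(self):
        # node with k=4, e=3 -> 0.5
        net = build_network(
            [("x", n, 0.5) for n in "ABCD"]
            + [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5)]
        )
        assert clustering_coefficient(net, "x") == 0.5

    def test_unknown_node_raises(self, triangle):
        with pytest.raises(KeyError):
            clustering_coefficient(triangle, "Z")


class TestBetweenness:
    def test_path_center_ordered(self, path4):
        # A-B-C: B lies on the single shortest path in both directions
        net = build_network([("A", "B", 0.5), ("B", "C", 0.5)])
        assert betweenness(net, "B", pair_mode="ordered") == 2.0

    def test_star_center(self, star4):
        assert betweenness(star4, "hub", pair_mode="ordered") == 12.0

    def test_leaf_is_zero(self, star4):
        assert betweenness(star4, "A") == 0.0

    def test_ordered_is_twice_unordered(self, path4):
        for n in path4.nodes:
            assert betweenness(path4, n, "ordered") == 2 * betweenness(
                path4, n, "unordered"
            )

    def test_disconnected_pairs_contribute_zero(self):
        net = build_network([("A", "B", 0.5), ("C", "D", 0.5)])
        assert betweenness(net, "A") == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_path_enumeration(self, seed):
        adj = random_adj(np.random.default_rng(seed))
        net = net_from_adj(adj)
        bc = betweenness_all(net, pair_mode="ordered")
        for w in adj:
            assert bc[w] == pytest.approx(brute_betweenness(adj, w), abs=1e-9)

    @pytest.mark.parametrize("length", range(3, 11))
    def test_path_graph_total_matches_enumeration(self, length):
        nodes = [f"p{i:02d}" for i in range(length)]
        edges = [(nodes[i], nodes[i + 1], 0.5) for i in range(length - 1)]
        net = build_network(edges)
        adj = {n: set(net.neighbors(n)) for n in net.nodes}
        total = sum(betweenness_all(net).values())
        expected = sum(brute_betweenness(adj, w) for w in adj)
        assert total == pytest.approx(expected, abs=1e-9)


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self, star3):
        assert degree_assortativity(star3, formula="corrected") == pytest.approx(-1.0)

    def test_path4_value(self, path4):
        assert degree_assortativity(path4) == pytest.approx(-0.5)

    def test_cycle_is_degenerate(self):
        net = build_network(
            [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5), ("D", "A", 0.5)]
        )
        assert degree_assortativity(net) is None

    def test_edgeless_network_warns_undefined(self):
        from netpharm.types import InteractionNetwork

        net = InteractionNetwork()
        net.add_node("A")
        with pytest.warns(UserWarning):
            assert degree_assortativity(net) is None

    def test_as_printed_leaves_unit_interval_on_star(self, star3):
        """The literal formula yields 5/3 on the 3-leaf star — outside [-1, 1]."""
        v = degree_assortativity(star3, formula="as_printed")
        assert v == pytest.approx(5.0 / 3.0)
        assert abs(v) > 1

    @pytest.mark.parametrize("seed", range(20))
    def test_corrected_matches_independent_pearson_and_is_bounded(self, seed):
        adj = random_adj(np.random.default_rng(seed + 1000))
        net = net_from_adj(adj)
        if net.number_of_edges() == 0:
            return
        v = degree_assortativity(net, method="pcc", formula="corrected")
        deg = {n: len(adj[n]) for n in adj}
        xs, ys = [], []
        for u in adj:
            for w in adj[u]:
                xs.append(deg[u])
                ys.append(deg[w])
        if len(set(xs)) == 1:
            assert v is None
        else:
            assert v == pytest.approx(brute_pearson(xs, ys), abs=1e-9)
            assert -1 <= v <= 1


class TestDegreeDistribution:
    def test_star(self, star3):
        assert degree_distribution(star3) == {1: 0.75, 3: 0.25}

    def test_edgeless(self):
        from netpharm.types import InteractionNetwork

        net = InteractionNetwork()
        for n in "ABCDE":
            net.add_node(n)
        assert degree_distribution(net) == {0: 1.0}

    def test_triangle(self, triangle):
        assert degree_distribution(triangle) == {2: 1.0}

    def test_fractions_sum_to_one(self):
        adj = random_adj(np.random.default_rng(5))
        dist = degree_distribution(net_from_adj(adj))
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_summary_bundles_everything(self, star3):
        s = network_summary(star3)
        assert s.degree_distribution[1] == 0.75
        assert s.assortativity_pcc == pytest.approx(-1.0)
        assert s.assortativity_scc == pytest.approx(-1.0)
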