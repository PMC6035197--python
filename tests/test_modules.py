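"""Module extraction, normalization and the combined MC score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_network

from netpharm.errors import ValidationError
from netpharm.fixtures import FixtureSpec, gen_planted
from netpharm.modules import (
    extract_module,
    mc_score,
    min_max_normalize,
    module_strength,
    rank_nodes,
)
from netpharm.types import McWeights


class TestExtractModule:
    def test_fewer_neighbors_than_k(self, triangle):
        mod = extract_module(triangle, "A", k=10)
        assert mod.genes == ["B", "C"]

    def test_lexicographic_tie_break(self):
        net = build_network([("s", "B", 0.9), ("s", "C", 0.9), ("s", "D", 0.8)])
        mod = extract_module(net, "s", k=2)
        assert mod.genes == ["B", "C"]

    def test_top_k_equals_full_sort_truncation(self):
        rng = np.random.default_rng(42)
        weights = {f"n{i:02d}": float(w) for i, w in enumerate(rng.uniform(0.1, 1, 15))}
        net = build_network([("seed", n, w) for n, w in weights.items()])
        mod = extract_module(net, "seed", k=10)
        expected = sorted(weights, key=lambda n: (-weights[n], n))[:10]
        assert mod.genes == expected

    def test_missing_seed_raises(self, triangle):
        with pytest.raises(KeyError):
            extract_module(triangle, "nope")

    def test_isolated_seed_warns_empty(self):
        from netpharm.types import InteractionNetwork

        net = InteractionNetwork()
        net.add_node("alone")
        with pytest.warns(UserWarning, match="isolated"):
            mod = extract_module(net, "alone")
        assert mod.genes == []


class TestMinMaxNormalize:
    def test_basic(self):
        assert min_max_normalize({"a": 0, "b": 5, "c": 10}) == {
            "a": 0.0, "b": 0.5, "c": 1.0
        }

    def test_all_equal_maps_to_zero(self):
        assert min_max_normalize({"a": 7, "b": 7}) == {"a": 0.0, "b": 0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            min_max_normalize({})

    @settings(derandomize=True, max_examples=50)
    @given(
        st.dictionaries(
            st.text("abcdefgh", min_size=1, max_size=4),
            st.floats(-1e6, 1e6),
            min_size=1,
            max_size=20,
        )
    )
    def test_range_and_monotonicity_hold_for_any_input(self, values):
        normed = min_max_normalize(values)
        assert all(0.0 <= v <= 1.0 for v in normed.values())
        for a in values:
            for b in values:
                if values[a] < values[b]:
                    assert normed[a] <= normed[b]

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        vals = {f"n{i}": float(v) for i, v in enumerate(rng.normal(size=100))}
        normed = min_max_normalize(vals)
        order_in = sorted(vals, key=vals.get)
        order_out = sorted(normed, key=normed.get)
        assert order_in == order_out


class TestMcScore:
    def worked_components(self):
        nodes = ["a", "b", "c"]
        return dict(
            ces=dict(zip(nodes, [0.0, 1.0, 2.0])),
            gos=dict(zip(nodes, [2.0, 2.0, 2.0])),
            clc=dict(zip(nodes, [0.0, 0.5, 1.0])),
            bwc=dict(zip(nodes, [4.0, 0.0, 2.0])),
            don=dict(zip(nodes, [1.0, 2.0, 3.0])),
        )

    def test_worked_example(self):
        scores = {s.node: s.mc for s in mc_score(**self.worked_components())}
        # gos is all-equal and normalizes to zero everywhere
        assert scores == pytest.approx({"a": 1.0, "b": 1.5, "c": 3.5})

    def test_extremes_with_unit_weights(self):
        comps = {
            name: {"lo": 0.0, "hi": 1.0} for name in ("ces", "gos", "clc", "bwc", "don")
        }
        scores = {s.node: s.mc for s in mc_score(**comps)}
        assert scores["hi"] == 5.0 and scores["lo"] == 0.0

    def test_weight_linearity_and_zeroing(self):
        comps = self.worked_components()
        base = {s.node: s.mc for s in mc_score(**comps)}
        double = {s.node: s.mc for s in mc_score(**comps, weights=McWeights(2, 2, 2, 2, 2))}
        for n in base:
            assert double[n] == pytest.approx(2 * base[n])
        # zero the bwc weight: mc becomes independent of that component
        no_bwc = mc_score(**comps, weights=McWeights(1, 1, 1, 0, 1))
        comps2 = dict(comps, bwc={"a": 100.0, "b": 3.0, "c": 0.0})
        no_bwc2 = mc_score(**comps2, weights=McWeights(1, 1, 1, 0, 1))
        assert {s.node: s.mc for s in no_bwc} == {s.node: s.mc for s in no_bwc2}

    def test_mismatched_node_sets_rejected(self):
        comps = self.worked_components()
        del comps["don"]["c"]
        with pytest.raises(ValidationError, match="don"):
            mc_score(**comps)

    def test_permutation_invariance(self):
        net, _ = gen_planted(FixtureSpec(seed=2, n_nodes=20, planted_size=5))
        scores = rank_nodes(net, k=5)
        mapping = {n: f"X{n}" for n in net.nodes}
        from netpharm.types import InteractionNetwork

        relabeled = InteractionNetwork(score_scale="unit")
        for n in net.nodes:
            relabeled.add_node(mapping[n])
        for u, v in net.edges:
            relabeled.add_edge(mapping[u], mapping[v], net.weight(u, v))
        scores2 = rank_nodes(relabeled, k=5)
        assert {mapping[s.node]: s.mc for s in scores} == pytest.approx(
            {s.node: s.mc for s in scores2}
        )


class TestModuleStrength:
    def test_within_module_only(self):
        net = build_network(
            [("s", "A", 0.9), ("s", "B", 0.8), ("A", "B", 0.5), ("A", "Z", 0.7)]
        )
        mod = extract_module(net, "s", k=2)  # members A, B; Z excluded
        ces = module_strength(net, mod)
        assert ces["A"] == pytest.approx(0.9 + 0.5)  # edge to Z not counted
        assert ces["s"] == pytest.approx(0.9 + 0.8)


class TestPlantedRecovery:
    def test_planted_nodes_rank_above_background(self):
        """Dense high-confidence planted modules rise to the top of the MC ranking."""
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            net, planted = gen_planted(FixtureSpec(seed=seed))
            ranking = rank_nodes(net, k=10)
            pos = {s.node: i for i, s in enumerate(ranking)}
            mean_p = np.mean([pos[n] for n in planted])
            mean_b = np.mean([pos[n] for n in net.nodes if n not in planted])
            if mean_p < mean_b:
                wins += 1
        assert wins >= 0.95 * n_rep
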