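"""Propagated GO node score and the combined namespace scores."""

import numpy as np
import pytest

from oracles import brute_term_score

from netpharm.fixtures import FixtureSpec, gen_dag
from netpharm.go_scoring import (
    GoScoreParams,
    descendant_distances,
    namespace_scores,
    term_score,
)
from netpharm.types import GoAnnotation, GoDag


def dag_with(terms, links, ns="biological_process"):
    dag = GoDag()
    for t in terms:
        dag.add_term(t, t, ns)
    for child, parent in links:
        dag.add_is_a(child, parent)
    dag.validate()
    return dag


class TestTermScore:
    def test_leaf_with_direct_annotations_only(self):
        dag = dag_with(["leaf"], [])
        ann = GoAnnotation.from_pairs([(f"g{i}", "leaf") for i in range(3)], dag)
        assert term_score(dag, ann, "leaf", GoScoreParams(alpha=0.5)) == 3.0

    def test_two_level_propagation(self):
        # gp(g)=2, child gp=1 at dist 1, grandchild gp=4 at dist 2, alpha=0.5
        dag = dag_with(["g", "c", "gc"], [("c", "g"), ("gc", "c")])
        pairs = (
            [(f"a{i}", "g") for i in range(2)]
            + [("b0", "c")]
            + [(f"d{i}", "gc") for i in range(4)]
        )
        ann = GoAnnotation.from_pairs(pairs, dag)
        assert term_score(dag, ann, "g", GoScoreParams(alpha=0.5)) == pytest.approx(
            2 + 1 * 0.5 + 4 * 0.25
        )

    def test_unannotated_descendants_score_zero(self):
        dag = dag_with(["g", "c"], [("c", "g")])
        ann = GoAnnotation.from_pairs([("x", "c")], dag)
        empty = GoAnnotation.from_pairs([], dag)
        assert term_score(dag, empty, "g") == 0.0
        assert term_score(dag, ann, "c", GoScoreParams(include_self=False)) == 0.0

    def test_unknown_term_raises(self, chain_dag, chain_annotation):
        with pytest.raises(KeyError):
            term_score(chain_dag, chain_annotation, "nope")

    def test_multi_path_distance_is_minimum(self):
        # diamond: leaf is_a a, leaf is_a b; a is_a root at 1; b is_a mid is_a root
        dag = dag_with(
            ["root", "mid", "a", "b", "leaf"],
            [("a", "root"), ("mid", "root"), ("b", "mid"),
             ("leaf", "a"), ("leaf", "b")],
        )
        assert descendant_distances(dag, "root")["leaf"] == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle(self, seed):
        spec = FixtureSpec(seed=seed, dag_layers=4, dag_branching=2,
                           annotation_rate=0.1, n_genes=12)
        dag, ann = gen_dag(spec)
        gp = ann.gene_counts()
        params = GoScoreParams(alpha=0.6)
        for t in dag.terms:
            expected = brute_term_score(dag.parents, gp, t, 0.6)
            assert term_score(dag, ann, t, params) == pytest.approx(
                expected, abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_alpha_and_annotation(self, seed):
        dag, ann = gen_dag(FixtureSpec(seed=seed, annotation_rate=0.1))
        lo, hi = GoScoreParams(alpha=0.3), GoScoreParams(alpha=0.9)
        for t in dag.terms:
            assert term_score(dag, ann, t, hi) >= term_score(dag, ann, t, lo)
        # adding one annotation to a descendant strictly increases the score
        root = next(t for t in dag.terms if not dag.parents[t])
        desc = sorted(descendant_distances(dag, root))
        target = desc[-1]
        before = term_score(dag, ann, root)
        ann2 = GoAnnotation(assignments=set(ann.assignments) | {("new_gene", target)})
        assert term_score(dag, ann2, root) > before


class TestNamespaceScores:
    def test_single_namespace_chain(self, chain_dag, chain_annotation):
        scores = namespace_scores(
            chain_dag, chain_annotation, {"gene1"}, GoScoreParams(alpha=0.5)
        )
        assert scores.bps == pytest.approx(1 + 0.5 + 0.25)
        assert scores.mfs == 0.0 and scores.ccs == 0.0
        assert scores.gos == pytest.approx(1.75)

    def test_gos_is_exact_sum(self):
        dag, ann = gen_dag(FixtureSpec(seed=9, annotation_rate=0.2))
        scores = namespace_scores(dag, ann, ann.genes())
        assert scores.gos - (scores.bps + scores.mfs + scores.ccs) == 0.0

    def test_unannotated_gene_warns_and_contributes_zero(self, chain_dag, chain_annotation):
        with pytest.warns(UserWarning, match="no annotations"):
            scores = namespace_scores(chain_dag, chain_annotation,
                                      {"gene1", "ghost"})
        only = namespace_scores(chain_dag, chain_annotation, {"gene1"})
        assert scores.gos == only.gos

    def test_empty_annotation_set_is_all_zero(self, chain_dag):
        empty = GoAnnotation()
        with pytest.warns(UserWarning):
            scores = namespace_scores(chain_dag, empty, {"g"})
        assert (scores.bps, scores.mfs, scores.ccs, scores.gos) == (0, 0, 0, 0)

    def test_empty_gene_set_rejected(self, chain_dag, chain_annotation):
        with pytest.raises(ValueError):
            namespace_scores(chain_dag, chain_annotation, set())
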