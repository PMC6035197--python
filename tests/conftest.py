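import pytest

from netpharm.types import GoAnnotation, GoDag, InteractionNetwork


def build_network(edges, scale="unit"):
    """Network from [(u, v, w)] triples."""
    net = InteractionNetwork(score_scale=scale)
    for u, v, w in edges:
        net.add_edge(u, v, w)
    return net


def net_from_adj(adj):
    """Unweighted-topology network from an adjacency dict (weight 0.5)."""
    net = InteractionNetwork(score_scale="unit")
    for n in adj:
        net.add_node(n)
    for u, nbrs in adj.items():
        for v in nbrs:
            if u < v:
                net.add_edge(u, v, 0.5)
    return net


@pytest.fixture
def triangle():
    return build_network([("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7)])


@pytest.fixture
def path4():
    return build_network([("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5)])


@pytest.fixture
def star4():
    """Hub with four leaves."""
    return build_network([("hub", leaf, 0.5) for leaf in "ABCD"])


@pytest.fixture
def star3():
    return build_network([("hub", leaf, 0.5) for leaf in "ABC"])


@pytest.fixture
def chain_dag():
    """Three BP terms in an is_a chain: leaf -> mid -> root."""
    dag = GoDag()
    for t in ("root", "mid", "leaf"):
        dag.add_term(t, t, "biological_process")
    dag.add_is_a("mid", "root")
    dag.add_is_a("leaf", "mid")
    dag.validate()
    return dag


@pytest.fixture
def chain_annotation(chain_dag):
    return GoAnnotation.from_pairs([("gene1", "leaf")], chain_dag)
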