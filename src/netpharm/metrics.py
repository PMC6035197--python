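"""Graph statistics of the interaction network.

Per-node: degree, local clustering coefficient C_i = 2e / (k(k-1)),
betweenness centrality C_b(w) = sum over pairs of sigma_ij(w)/sigma_ij
(unweighted shortest paths, unnormalized), and strength (sum of incident
edge weights). Network-level: the degree distribution p(k) and degree
assortativity as the correlation between the degrees found at the two
endpoints of each edge.

Edge weights are interaction confidences, not distances, so all shortest
paths here are unweighted. Betweenness defaults to *ordered* pair
counting — (i, j) and (j, i) are counted separately, which on an
undirected graph is exactly twice the conventional unordered value.

The assortativity formula exists in two variants. ``corrected`` (default)
is the standard degree-correlation coefficient: the Pearson (or Spearman)
correlation over the 2M ordered endpoint-degree pairs, guaranteed to lie
in [-1, 1]. ``as_printed`` subtracts the *mean of the squared* half-sum
instead of the squared mean — a formula that can leave [-1, 1] (it gives
5/3 on the 3-leaf star) and is kept only so the discrepancy can be
demonstrated and documented.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Dict, List, Optional

import networkx as nx
import numpy as np
from scipy import stats

from .types import InteractionNetwork, NetworkSummary, NodeMetrics


def clustering_coefficient(net: InteractionNetwork, i: str) -> float:
    """Local clustering coefficient C_i = 2e / (k(k-1)); 0 when k < 2."""
    nbrs = list(net.neighbors(i))  # raises KeyError for unknown nodes
    k = len(nbrs)
    if k < 2:
        return 0.0
    g = net.graph
    e = sum(
        1
        for a in range(k)
        for b in range(a + 1, k)
        if g.has_edge(nbrs[a], nbrs[b])
    )
    return 2.0 * e / (k * (k - 1))


def betweenness(
    net: InteractionNetwork, w: str, pair_mode: str = "ordered"
) -> float:
    """Betweenness centrality of node ``w`` over unweighted shortest paths.

    Disconnected pairs contribute 0; no normalization is applied.
    ``pair_mode="ordered"`` (default) counts (i, j) and (j, i) separately.
    """
    return betweenness_all(net, pair_mode=pair_mode)[w]


def betweenness_all(
    net: InteractionNetwork, pair_mode: str = "ordered"
) -> Dict[str, float]:
    """Betweenness for every node at once (Brandes accumulation)."""
    if pair_mode not in ("ordered", "unordered"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    bc = nx.betweenness_centrality(net.graph, normalized=False, weight=None)
    factor = 2.0 if pair_mode == "ordered" else 1.0
    return {n: factor * v for n, v in bc.items()}


def degree_distribution(net: InteractionNetwork) -> Dict[int, float]:
    """p(k): fraction of nodes having degree k. Fractions sum to 1."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("degree distribution undefined for an empty network")
    counts = Counter(d for _, d in net.graph.degree())
    return {k: c / n for k, c in sorted(counts.items())}


def _endpoint_degree_pairs(net: InteractionNetwork) -> np.ndarray:
    """The 2M ordered endpoint-degree pairs (j_i, k_i), one per edge end."""
    deg = dict(net.graph.degree())
    pairs = []
    for u, v in net.edges:
        pairs.append((deg[u], deg[v]))
        pairs.append((deg[v], deg[u]))
    return np.asarray(pairs, dtype=float)


def degree_assortativity(
    net: InteractionNetwork,
    method: str = "pcc",
    formula: str = "corrected",
) -> Optional[float]:
    """Degree assortativity of an undirected network.

    Returns None (undefined) on edgeless networks and, for the corrected
    formula, when every endpoint degree is equal (zero variance).
    """
    if method not in ("pcc", "scc"):
        raise ValueError(f"unknown method {method!r}")
    if formula not in ("corrected", "as_printed"):
        raise ValueError(f"unknown formula {formula!r}")
    if net.number_of_edges() == 0:
        warnings.warn("assortativity undefined on an edgeless network", stacklevel=2)
        return None

    pairs = _endpoint_degree_pairs(net)
    j, k = pairs[:, 0], pairs[:, 1]

    if formula == "as_printed":
        # literal transcription: the subtracted term is the mean of the
        # SQUARED half-sum, not the square of the mean — can exceed |1|
        m1_jk = float(np.mean(j * k))
        m1_sq = float(np.mean(0.5 * (j + k) ** 2))
        denom = float(np.mean(0.5 * (j**2 + k**2))) - m1_sq
        if denom == 0:
            return None
        return (m1_jk - m1_sq) / denom

    if np.ptp(j) == 0 and np.ptp(k) == 0:
        return None
    if method == "pcc":
        r = stats.pearsonr(j, k).statistic
    else:
        r = stats.spearmanr(j, k).statistic
    return None if np.isnan(r) else float(r)


def node_metrics(net: InteractionNetwork) -> List[NodeMetrics]:
    """Degree, clustering, betweenness (ordered) and strength per node."""
    bc = betweenness_all(net, pair_mode="ordered")
    return [
        NodeMetrics(
            node=n,
            degree=net.degree(n),
            clustering=clustering_coefficient(net, n),
            betweenness=bc[n],
            strength=net.strength(n),
        )
        for n in sorted(net.nodes)
    ]


def network_summary(net: InteractionNetwork) -> NetworkSummary:
    """Degree distribution plus both assortativity coefficients."""
    return NetworkSummary(
        degree_distribution=degree_distribution(net),
        assortativity_pcc=degree_assortativity(net, method="pcc"),
        assortativity_scc=degree_assortativity(net, method="scc"),
    )
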