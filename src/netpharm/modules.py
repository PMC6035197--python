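"""Co-expression module extraction and combined Module Construction scoring.

A module is a seed target plus its top-k interaction partners by edge
confidence ("top ten co-expressed genes" in the default configuration).
Nodes are then ranked by the Module Construction (MC) score, a weighted
sum of five per-node components:

    MC = w_ces*CES + w_gos*GOS + w_clc*CLC + w_bwc*BWC + w_don*DON

where CES is the co-expression score (within-module strength: sum of edge
confidences linking the node into its module), GOS the gene ontology
score, CLC the local clustering coefficient, BWC betweenness centrality
and DON the node degree. The five components live on incommensurable
scales, so each is min-max normalized to [0, 1] independently before the
weighted sum; weights default to 1.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

from .errors import ValidationError
from .go_scoring import GoScoreParams, namespace_scores
from .metrics import betweenness_all, clustering_coefficient
from .types import (
    CoexpressionModule,
    GoAnnotation,
    GoDag,
    InteractionNetwork,
    McWeights,
    ModuleScore,
)

COMPONENTS = ("ces", "gos", "clc", "bwc", "don")


def extract_module(
    net: InteractionNetwork, seed: str, k: int = 10
) -> CoexpressionModule:
    """The k highest-confidence neighbors of ``seed``.

    Ties are broken lexicographically by gene id; the seed itself is never
    a member. An isolated seed yields an empty module with a warning.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    nbrs = sorted(
        ((nb, net.normalized_weight(seed, nb)) for nb in net.neighbors(seed)),
        key=lambda item: (-item[1], item[0]),
    )
    if not nbrs:
        warnings.warn(f"seed {seed!r} is isolated; empty module", stacklevel=2)
    return CoexpressionModule(seed=seed, members=nbrs[:k], k=k)


def min_max_normalize(values: Dict[str, float]) -> Dict[str, float]:
    """Map values onto [0, 1] by (v - min)/(max - min).

    Degenerate all-equal inputs map uniformly to 0.0.
    """
    if not values:
        raise ValueError("cannot normalize an empty mapping")
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {n: 0.0 for n in values}
    span = hi - lo
    return {n: (v - lo) / span for n, v in values.items()}


def mc_score(
    ces: Dict[str, float],
    gos: Dict[str, float],
    clc: Dict[str, float],
    bwc: Dict[str, float],
    don: Dict[str, float],
    weights: Optional[McWeights] = None,
) -> List[ModuleScore]:
    """Combined MC score per node, ranked descending (ties lexicographic).

    All five component maps must share one node set.
    """
    weights = weights or McWeights()
    comps = {"ces": ces, "gos": gos, "clc": clc, "bwc": bwc, "don": don}
    node_set = set(ces)
    for name, comp in comps.items():
        diff = node_set ^ set(comp)
        if diff:
            raise ValidationError(
                f"component {name!r} node set mismatch: {sorted(diff)}"
            )
    if not node_set:
        raise ValueError("no nodes to score")

    norm = {name: min_max_normalize(comp) for name, comp in comps.items()}
    wvec = {
        "ces": weights.w_ces,
        "gos": weights.w_gos,
        "clc": weights.w_clc,
        "bwc": weights.w_bwc,
        "don": weights.w_don,
    }
    scores = []
    for n in node_set:
        mc = sum(wvec[name] * norm[name][n] for name in COMPONENTS)
        scores.append(
            ModuleScore(
                node=n,
                ces=ces[n],
                gos=gos[n],
                clc=clc[n],
                bwc=bwc[n],
                don=don[n],
                norm={name: norm[name][n] for name in COMPONENTS},
                mc=mc,
            )
        )
    scores.sort(key=lambda s: (-s.mc, s.node))
    return scores


def module_strength(net: InteractionNetwork, module: CoexpressionModule) -> Dict[str, float]:
    """CES per node: sum of edge confidences linking it into the module.

    The node set is the seed plus the module members; edges outside that
    set do not count.
    """
    nodes = [module.seed] + module.genes
    node_set = set(nodes)
    out = {}
    for n in nodes:
        out[n] = sum(
            net.normalized_weight(n, nb)
            for nb in net.neighbors(n)
            if nb in node_set
        )
    return out


def rank_nodes(
    net: InteractionNetwork,
    k: int = 10,
    dag: Optional[GoDag] = None,
    ann: Optional[GoAnnotation] = None,
    go_params: Optional[GoScoreParams] = None,
    weights: Optional[McWeights] = None,
    nodes: Optional[Sequence[str]] = None,
) -> List[ModuleScore]:
    """Score and rank nodes of a network by the combined MC score.

    Each node's CES is its within-module strength, the module being its own
    top-k neighborhood. GOS per node is the gene's ontology score (zero
    when no DAG/annotation is supplied). CLC, BWC and DON come from the
    full network.
    """
    node_list = sorted(net.nodes) if nodes is None else list(nodes)
    if not node_list:
        raise ValueError("network has no nodes to rank")
    bwc_all = betweenness_all(net, pair_mode="ordered")

    ces, gos, clc, bwc, don = {}, {}, {}, {}, {}
    gp = ann.gene_counts() if ann is not None else None
    for n in node_list:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = extract_module(net, n, k=k)
            ces[n] = module_strength(net, mod)[n]
            if dag is not None and ann is not None:
                gos[n] = namespace_scores(dag, ann, {n}, go_params).gos
            else:
                gos[n] = 0.0
        clc[n] = clustering_coefficient(net, n)
        bwc[n] = bwc_all[n]
        don[n] = float(net.degree(n))
    return mc_score(ces, gos, clc, bwc, don, weights=weights)
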