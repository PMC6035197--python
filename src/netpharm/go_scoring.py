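"""Descendant-propagated GO node scores and the combined Gene Ontology Score.

The score of a term ``g`` aggregates the annotation counts of its
descendants, discounted geometrically with distance:

    score(g) = sum over g_a in desc(g) of gp(g_a) * alpha^dist(g, g_a)

where ``gp(g_a)`` is the number of distinct genes directly annotated to
``g_a``, ``dist`` is the minimum number of ``is_a`` edges from ``g_a`` up
to ``g``, and ``desc(g)`` includes ``g`` itself at distance 0 (the default;
``include_self=False`` gives the strict descendants-only reading).

Per gene set, term scores are summed within each namespace to give the
Biological Process Score (BPS), Molecular Function Score (MFS) and
Cellular Component Score (CCS); the overall Gene Ontology Score is their
sum: GOS = BPS + MFS + CCS.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Dict, Optional, Set

from .types import GoAnnotation, GoDag, GO_NAMESPACES


@dataclass
class GoScoreParams:
    """Tunables of the propagated node score.

    alpha
        Distance-decay factor in (0, 1]; each extra ``is_a`` edge between
        a descendant and the scored term multiplies its contribution by
        ``alpha``. Default 0.6.
    include_self
        Whether the scored term itself contributes at distance 0.
    """

    alpha: float = 0.6
    include_self: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass
class GoScores:
    """Per-term scores plus the namespace sums and their total."""

    term_scores: Dict[str, float]
    bps: float
    mfs: float
    ccs: float

    @property
    def gos(self) -> float:
        return self.bps + self.mfs + self.ccs


def descendant_distances(dag: GoDag, g: str) -> Dict[str, int]:
    """Minimum ``is_a`` edge count from each descendant of ``g`` up to ``g``.

    Includes ``g`` itself at distance 0. BFS downward over the child index
    yields minimum distances directly.
    """
    if g not in dag:
        raise KeyError(f"unknown GO term {g!r}")
    children = dag.children
    dist = {g: 0}
    queue = deque([g])
    while queue:
        t = queue.popleft()
        for c in children.get(t, ()):
            if c not in dist:
                dist[c] = dist[t] + 1
                queue.append(c)
    return dist


def term_score(
    dag: GoDag,
    ann: GoAnnotation,
    g: str,
    params: Optional[GoScoreParams] = None,
    _gp: Optional[Dict[str, int]] = None,
) -> float:
    """Propagated annotation score of a single GO term.

    ``_gp`` optionally supplies precomputed direct-annotation counts
    (e.g. restricted to a gene subset) to avoid recomputation in loops.
    """
    params = params or GoScoreParams()
    gp = ann.gene_counts() if _gp is None else _gp
    total = 0.0
    for term, d in descendant_distances(dag, g).items():
        if d == 0 and not params.include_self:
            continue
        n = gp.get(term, 0)
        if n:
            total += n * params.alpha**d
    return total


def namespace_scores(
    dag: GoDag,
    ann: GoAnnotation,
    genes: Set[str],
    params: Optional[GoScoreParams] = None,
) -> GoScores:
    """BPS / MFS / CCS / GOS for a gene set.

    Annotations are restricted to ``genes`` first; each namespace score is
    the sum of ``term_score`` over that namespace's terms whose descendant
    closure carries at least one restricted annotation. Genes without any
    annotation contribute zero (with a warning).
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    params = params or GoScoreParams()
    annotated = ann.genes()
    orphans = set(genes) - annotated
    if orphans:
        warnings.warn(
            f"{len(orphans)} gene(s) with no annotations contribute 0: "
            f"{sorted(orphans)[:5]}",
            stacklevel=2,
        )
    gp = ann.gene_counts(genes=set(genes))
    per_ns = dict.fromkeys(GO_NAMESPACES, 0.0)
    term_scores: Dict[str, float] = {}
    for t in dag.terms:
        s = term_score(dag, ann, t, params, _gp=gp)
        if s > 0:
            term_scores[t] = s
            per_ns[dag.namespace(t)] += s
    return GoScores(
        term_scores=term_scores,
        bps=per_ns["biological_process"],
        mfs=per_ns["molecular_function"],
        ccs=per_ns["cellular_component"],
    )
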