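"""Map co-expression modules onto reference pathway gene sets.

Overlap between a module and each pathway is scored with the
hypergeometric upper tail: the probability of drawing at least the
observed overlap when |module| genes are sampled without replacement from
a universe containing |pathway| successes. P-values are corrected across
the pathways tested for one module with Benjamini–Hochberg.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Set

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .types import PathwayGeneSet, PathwayHit


def hypergeom_tail(overlap: int, universe: int, pathway: int, module: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, pathway, module)."""
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, pathway, module))


def map_module(
    module_genes: Set[str],
    pathways: Sequence[PathwayGeneSet],
    universe: Set[str],
    module_seed: str = "",
) -> List[PathwayHit]:
    """Rank pathways by hypergeometric overlap with one module.

    Every pathway is intersected with the universe before testing; the
    module must be a subset of the universe. Hits come back ordered by
    (p-value, pathway id), with BH q-values across all pathways tested.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    offenders = set(module_genes) - set(universe)
    if offenders:
        raise ValidationError(
            f"module genes outside the universe: {sorted(offenders)}"
        )
    hits = []
    n_univ = len(universe)
    n_mod = len(module_genes)
    for pw in pathways:
        members = pw.members & universe
        overlap = frozenset(module_genes & members)
        p = hypergeom_tail(len(overlap), n_univ, len(members), n_mod)
        hits.append(
            PathwayHit(
                pathway_id=pw.pathway_id,
                module_seed=module_seed,
                overlap_genes=overlap,
                overlap_size=len(overlap),
                pathway_size=len(members),
                module_size=n_mod,
                universe_size=n_univ,
                p_value=p,
                q_value=1.0,
            )
        )
    if hits:
        _, qvals, _, _ = multipletests(
            [h.p_value for h in hits], method="fdr_bh"
        )
        for h, q in zip(hits, qvals):
            h.q_value = float(q)
    hits.sort(key=lambda h: (h.p_value, h.pathway_id))
    return hits


def default_universe(
    network_nodes: Optional[Set[str]], pathways: Sequence[PathwayGeneSet]
) -> Set[str]:
    """Union of network nodes and all pathway members."""
    universe: Set[str] = set(network_nodes or ())
    for pw in pathways:
        universe |= pw.members
    return universe
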