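"""Rank and filter externally produced docking results.

The screening criterion is the classic rigid-docking pair: high geometric
shape complementarity score, low (most negative) atomic contact energy.
Each record gets one rank per key (competition ranking: ties share the
better rank) and a combined ordering by the sum of the two ranks, ties
broken by PDB id.
"""

from __future__ import annotations

import warnings
from typing import List, Set

from scipy.stats import rankdata

from .types import DockingRanking, DockingRecord

RANK_KEYS = ("geom", "ace", "combined")


def rank_docking(records: List[DockingRecord]) -> DockingRanking:
    """Assign geometric, ACE and combined ranks to docking records.

    geom_rank 1 = largest geometric score; ace_rank 1 = most negative ACE;
    combined order sorts by geom_rank + ace_rank, then PDB id. The result
    is invariant under permutation of the input records.
    """
    if not records:
        raise ValueError("cannot rank an empty record list")
    geom = rankdata([-r.geom_score for r in records], method="min")
    ace = rankdata([r.ace for r in records], method="min")
    geom_rank = {i: int(g) for i, g in enumerate(geom)}
    ace_rank = {i: int(a) for i, a in enumerate(ace)}
    combined = sorted(
        range(len(records)),
        key=lambda i: (geom_rank[i] + ace_rank[i], records[i].pdb_id, i),
    )
    return DockingRanking(
        records=list(records),
        geom_rank=geom_rank,
        ace_rank=ace_rank,
        combined_order=combined,
    )


def select_targets(
    ranking: DockingRanking, top_n: int, by: str = "combined"
) -> Set[str]:
    """UniProt accessions of the top-n records under the chosen key.

    Duplicate accessions across rows keep their best (lowest) rank, so the
    returned set may be smaller than ``top_n``. Requesting more records
    than exist returns everything with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if by not in RANK_KEYS:
        raise ValueError(f"by must be one of {RANK_KEYS}")
    n = len(ranking.records)
    if top_n > n:
        warnings.warn(
            f"requested top {top_n} of only {n} records; returning all",
            stacklevel=2,
        )
        top_n = n
    if by == "combined":
        order = ranking.combined_order
    elif by == "geom":
        order = sorted(
            range(n), key=lambda i: (ranking.geom_rank[i], ranking.records[i].pdb_id)
        )
    else:
        order = sorted(
            range(n), key=lambda i: (ranking.ace_rank[i], ranking.records[i].pdb_id)
        )
    return {ranking.records[i].uniprot for i in order[:top_n]}
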