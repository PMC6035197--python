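# netpharm

Network analysis of drug–target interactions for natural-product
pharmacology. Given a small molecule's candidate targets — curated from
literature on one hand and predicted by pharmacophore mapping on the
other — `netpharm` screens and classifies the targets, scores gene sets
against the Gene Ontology, computes the interaction-network statistics
used for node prioritization, extracts and ranks co-expression modules,
maps modules onto reference pathways, and ranks externally produced
rigid-docking results. It is aimed at systems-pharmacology practitioners
who already have the external resources (STRING-style edge lists,
GO subsets, GMT pathway collections, PatchDock-style result tables) and
need a reproducible, scriptable pipeline over them.

## The method

**Screening.** Each candidate target carries two boolean evidence flags,
LM (literature mining) and PMR (pharmacophore mapping). Targets with
(+LM)(+PMR) are *primary* (PT); with (+LM)(−PMR) *secondary* (ST); a
pharmacophore-only target is a *predicted* target in the default mode
(an alternative published reading, selected with `mode="results_text"`,
calls pharmacophore-only targets secondary instead). Pharmacophore
records are pre-filtered by a fit threshold (default 30, inclusive) and a
reserve cap (default 300, highest fit first).

**GO scoring.** For a term *g* with descendant closure desc(*g*),

    score(g) = Σ_{g_a ∈ desc(g)} gp(g_a) · α^dist(g, g_a)

where gp counts genes directly annotated to *g_a*, dist is the minimum
number of `is_a` edges up to *g*, and α ∈ (0, 1] (default 0.6) discounts
distant descendants. Namespace sums give BPS, MFS and CCS, and
GOS = BPS + MFS + CCS.

**Network statistics.** Degree *k*, degree distribution p(k), local
clustering C_i = 2e/(k(k−1)), unnormalized betweenness
C_b(w) = Σ σ_ij(w)/σ_ij over ordered node pairs (unweighted shortest
paths), and degree assortativity as the Pearson or Spearman correlation
of the degrees at the two endpoints of each edge.

**Module construction.** A module is a primary target plus its top-k
(default 10) neighbors by interaction confidence. Nodes are ranked by

    MC = w₁·CES + w₂·GOS + w₃·CLC + w₄·BWC + w₅·DON

with CES the within-module strength, CLC clustering, BWC betweenness,
DON degree; each component is min-max normalized to [0, 1] before the
weighted sum (unit weights by default).

**Pathway mapping** scores module–pathway overlap with the
hypergeometric upper tail plus Benjamini–Hochberg correction.
**Docking screening** ranks result records by geometric shape
complementarity (higher better), atomic contact energy (lower better)
and the sum of the two ranks.

## Worked example

```python
from netpharm.docking import rank_docking, select_targets
from netpharm.fixtures import table1_fixture

records = table1_fixture("A")          # the shipped Picroside-I docking table
ranking = rank_docking(records)
best_ace = min(range(len(records)), key=lambda i: ranking.ace_rank[i])
print(records[best_ace].pdb_id, records[best_ace].ace)
print(sorted(select_targets(ranking, top_n=3, by="combined")))
```

prints

```
2RGS -614.34
['PDPK1', 'Q16539', 'TGFB2']
```

meaning: among the 12 docked Picroside-I complexes, the 2RGS complex has
the lowest (best) atomic contact energy of −614.34, and the three targets
that best balance contact energy with geometric shape complementarity
are PDPK1, Q16539 (p38 MAP kinase) and TGFB2. The scripts under
`examples/` walk through each capability the same way; `netpharm run
--config run.yaml` (or `netpharm simulate`, `screen`, `goscore`,
`metrics`, `modules`, `pathways`, `dock-rank`) exposes the stages from
the shell.

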