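# Methods

This note records the models implemented in `netpharm`, the defaults and
the design choices made where the procedure admitted more than one
reasonable reading.

## Evidence screening

Targets are classified from two independent evidence streams. The rule
with both flags set is uncontroversial (primary); the single-stream cases
exist in two published readings, so the classifier takes a `mode`
argument rather than guessing:

- `eq1` (default, the normative reading): literature-only → secondary,
  pharmacophore-only → predicted. "Predicted" is forced by exhaustive
  case analysis — a pharmacophore-only target has purely computational
  support and should not share a label with literature-backed targets.
- `results_text`: pharmacophore-only → secondary; literature-only
  targets are excluded with a warning, since under this reading they
  carry no in-silico interaction support.

The pharmacophore fit threshold (default 30) is **inclusive**
(`fit ≥ min_fit` retained): the source procedure does not state
strictness and the inclusive reading is conventional. Records flagged as
pharmacophore hits but lacking a fit score fail any positive threshold —
a missing score cannot attest to passing one. The reserve cap (default
300) keeps the highest-fit records, ties broken lexicographically by
target id so the cap is deterministic.

## GO scoring

`score(g) = Σ gp(g_a)·α^dist(g, g_a)` over the descendant closure of
`g`. Choices:

- **α = 0.6 by default**, configurable. The decay constant is not fixed
  by the procedure; 0.6 follows the annotation-propagation tooling this
  score descends from.
- **`desc(g)` includes `g` itself at distance 0** (`include_self=True`).
  Otherwise a fully annotated leaf term would score 0, which contradicts
  the score's use for prioritization. The strict descendants-only
  reading remains available.
- **dist is the minimum `is_a` edge count** over all upward paths —
  the standard graph distance; in a DAG a descendant can reach its
  ancestor along several chains.
- **gp counts direct annotations only** (after duplicate collapse).
  Counting closure annotations would propagate twice once combined with
  the α^dist discount.
- Namespace scores sum `term_score` **over terms** (not over genes);
  summing over genes would count a shared term once per gene and reduce
  to the same quantity only for disjoint annotation sets.
- Only `is_a` edges are read from OBO input; `part_of` and other
  relationships are ignored, because descendant propagation is defined
  on the subsumption hierarchy.

## Network statistics

- Shortest paths are **unweighted**: STRING-style weights are
  confidences, not distances.
- Betweenness is reported **raw** (no normalization) and, by default,
  over **ordered** pairs — exactly twice the unordered value on an
  undirected graph. The implementation delegates to Brandes
  accumulation (networkx) behind the package API; tests compare it
  against an independent path-enumeration oracle.
- Degree assortativity: the default `corrected` formula is the Pearson
  (or Spearman) correlation over the 2M ordered endpoint-degree pairs,
  which is bounded by construction and returns "undefined" (None) on
  degree-regular graphs (zero variance) and edgeless networks. The
  `as_printed` variant implements the literal published transcription,
  whose subtracted term is the mean of the squared half-sum rather than
  the square of the mean; it evaluates to 5/3 on the 3-leaf star, i.e.
  outside [−1, 1], and exists purely as a documented regression of that
  typo. Since a correlation coefficient must satisfy |r| ≤ 1, the
  corrected form is the default.
- Per-edge interaction confidence is taken from the input weights; the
  network-level assortativity is reported in the summary, not per edge.

## Module construction

The combined score `MC = Σ w_x · x̂` runs over five per-node components
(CES, GOS, CLC, BWC, DON), each min-max normalized to [0, 1]
independently before weighting. Rationale: the components live on
incommensurable scales (betweenness is unbounded, clustering is already
in [0, 1]); normalization makes unit weights meaningful. Degenerate
all-equal components normalize to 0 uniformly, dropping them from the
ranking rather than inflating it.

- **CES** is within-module strength: the sum of a node's edge
  confidences to other members of its module — the simplest per-node
  reduction of pairwise co-expression confidence.
- **DON** is the raw degree; normalization handles scale.
- Module extraction takes the k highest-confidence neighbors of a seed
  (default k = 10), ties broken lexicographically, so module membership
  is deterministic.
- In `rank_nodes`, each node's CES is computed against its own top-k
  neighborhood, which lets the ranking run without designating seeds;
  when seeds are given (the pipeline's primaries), their modules are
  reported alongside.

## Pathway mapping

The reference procedure mapped modules to pathways by manual literature
survey; that is not implementable, so the package substitutes the
standard algorithmic rendering: a hypergeometric upper-tail test of the
module–pathway overlap against a gene universe, with Benjamini–Hochberg
correction across the pathways tested per module. The universe defaults
to the union of network nodes and all pathway members and is
overridable — the choice materially changes p-values and must be
explicit. Pathways are intersected with the universe before testing.

## Docking screening

Records are ranked per key with competition ranking (ties share the
better rank): rank 1 is the largest geometric score and the most
negative contact energy respectively. The combined ordering sorts by the
rank sum, ties by PDB id — rank-sum is scale-free and monotone in both
criteria, which is all the screening rule asserts. Target selection
deduplicates by UniProt accession keeping the best-ranked record, since
selection feeds target-level downstream analysis.

## Synthetic data

The generators emulate each input format so the full pipeline runs
without any external download:

- **Networks**: uniform random (homogeneous degrees) and preferential
  attachment (heavy-tailed) models, with truncated-normal edge
  confidences on the declared scale (sd 0.05) — STRING-like bounded
  scores.
- **Planted module**: 8 of 50 nodes, internal density 0.9 and weight
  mean 0.9, against background density 0.05 and weight mean 0.3. These
  defaults define the recovery benchmark: with unit MC weights and
  k = 10, planted nodes should outrank background on average in at least
  95 of 100 seeded replicates.
- **Ontology**: a layered DAG per namespace (default 3 layers, branching
  2); each non-root term draws one or two parents from the layer above,
  so acyclicity holds by construction. Annotations are independent
  (gene, term) coin flips at the configured rate.
- **Evidence**: two target lists with an exactly-specified overlap count
  and uniform pharmacophore fits on [10, 100], so the default threshold
  of 30 is exercised on both sides.

What the synthetic data does *not* emulate: real degree-correlation
structure of curated interactomes, realistic GO term-size distributions,
annotation bias toward well-studied genes, and any correlation between
network position and annotation. Passing the planted-module benchmark
therefore shows the ranking recovers dense, high-confidence
neighborhoods under the stated effect size — not that it identifies
biological drug targets.

## Numerical and procedural choices

- Min-max normalization of an all-equal vector returns all zeros (no
  0/0).
- All rankings break ties lexicographically (node id, pathway id,
  PDB id) so outputs are order-independent and reproducible.
- STRING scores are accepted in the 0–1000 integer dialect or as 0–1
  reals, declared explicitly; weights are normalized to [0, 1] on
  access, never mutated in storage, so file round-trips are exact.
- Identifiers are case-sensitive and never aliased; joining gene symbols
  with UniProt accessions requires an explicit user-supplied mapping.
- Pipeline outputs are plain TSV with `repr`-formatted floats and no
  timestamps; identical inputs and configuration reproduce every output
  byte for byte. Stage isolation: each stage's TSV is a valid input for
  independent re-execution. Between-stage "cross validation" in the
  source procedure is unspecified; the pipeline validates all input
  paths up front and otherwise trusts completed stage outputs.
- The acceptance script and test suite use small problem sizes (graphs
  of ≤ 8 nodes for enumeration oracles, 100 replicates of 50-node
  networks for the recovery benchmark, universes ≤ 12 genes for
  exhaustive hypergeometric enumeration) — chosen so the brute-force
  oracles stay exact and the whole suite runs in seconds.

## Known limitations

- The per-edge "confidence" the assortativity formula's legend promises
  is taken from input weights; the formula itself yields one
  network-level number and is reported as such.
- GO scoring implements no enrichment p-values and no evidence-code
  filtering; it is a prioritization score, not a hypothesis test.
- The docking screen ranks externally produced results only; it neither
  runs docking nor inspects structures.
- Cross-namespace identifier resolution is out of scope by design.
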