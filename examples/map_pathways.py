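"""Hypergeometric module-to-pathway mapping.

The worked case: universe of 10 genes, a 5-gene pathway, a 4-gene module
overlapping it in all 4 genes. The upper-tail probability is
C(5,4)*C(5,0)/C(10,4) = 5/210.
"""

from netpharm.pathways import map_module
from netpharm.types import PathwayGeneSet

universe = {f"g{i}" for i in range(10)}
pathway = PathwayGeneSet("apoptosis", "toy pathway", frozenset({"g0", "g1", "g2", "g3", "g4"}))
background = PathwayGeneSet("unrelated", "toy background", frozenset({"g7", "g8", "g9"}))
module = {"g0", "g1", "g2", "g3"}

for hit in map_module(module, [pathway, background], universe, module_seed="CASP3"):
    print(f"{hit.pathway_id:10s} overlap={hit.overlap_size} "
          f"p={hit.p_value:.7f} q={hit.q_value:.7f}")
# apoptosis: p = 5/210 ~ 0.0238095 — the module is unlikely to hit all
# four pathway genes by chance; the unrelated set has p = 1.
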