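"""Graph statistics of a small interaction network.

Prints per-node degree, clustering and betweenness, the degree
distribution, and both assortativity variants on a 3-leaf star — the
corrected coefficient is -1 (perfectly disassortative), while the
literal-transcription variant escapes [-1, 1], which is why it is not the
default.
"""

from netpharm import InteractionNetwork
from netpharm.metrics import (
    betweenness_all,
    clustering_coefficient,
    degree_assortativity,
    degree_distribution,
)

net = InteractionNetwork(score_scale="unit")
for leaf in ("CASP1", "CASP3", "TGFB2"):
    net.add_edge("BRAF", leaf, 0.9)

bc = betweenness_all(net, pair_mode="ordered")
for n in sorted(net.nodes):
    print(f"{n:6s} degree={net.degree(n)} C_i={clustering_coefficient(net, n):.2f} "
          f"C_b={bc[n]:.1f}")
print("p(k):", degree_distribution(net))
print("assortativity (corrected):",
      degree_assortativity(net, formula="corrected"))
print("assortativity (as printed):",
      f"{degree_assortativity(net, formula='as_printed'):.4f}")
# Hub betweenness 6.0 = all 3*2 ordered leaf pairs route through BRAF.
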