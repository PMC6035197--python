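"""Recover a planted dense module with the combined MC ranking.

A synthetic 50-node network hides an 8-node module with high internal
density and confidence; the MC score (co-expression strength + GO score +
clustering + betweenness + degree, each min-max normalized) should place
the planted nodes at the top.
"""

from netpharm.fixtures import FixtureSpec, gen_planted
from netpharm.modules import rank_nodes

net, planted = gen_planted(FixtureSpec(seed=7))
scores = rank_nodes(net, k=10)

print("top 10 by MC score (* = planted):")
for s in scores[:10]:
    mark = "*" if s.node in planted else " "
    print(f" {mark} {s.node}  mc={s.mc:.3f}  ces={s.ces:.2f}  don={s.don:.0f}")

pos = {s.node: i + 1 for i, s in enumerate(scores)}
mean_planted = sum(pos[n] for n in planted) / len(planted)
print(f"mean rank of planted nodes: {mean_planted:.1f} of {len(scores)}")
# With the default effect size all or nearly all of the top ranks are
# planted nodes; the mean planted rank sits far above the background mean.
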