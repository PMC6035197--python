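"""Distance-discounted GO scoring of a gene set.

A term's score sums gp(descendant) * alpha^distance over its descendant
closure; per-namespace sums give BPS/MFS/CCS and their total, GOS.
"""

from netpharm import GoAnnotation, GoDag
from netpharm.go_scoring import GoScoreParams, namespace_scores, term_score

dag = GoDag()
for t in ("apoptosis", "caspase_activation", "casp3_activation"):
    dag.add_term(t, t.replace("_", " "), "biological_process")
dag.add_is_a("caspase_activation", "apoptosis")
dag.add_is_a("casp3_activation", "caspase_activation")

ann = GoAnnotation.from_pairs([("CASP3", "casp3_activation")], dag)
params = GoScoreParams(alpha=0.5)

for t in ("casp3_activation", "caspase_activation", "apoptosis"):
    print(f"score({t}) = {term_score(dag, ann, t, params):.4f}")

scores = namespace_scores(dag, ann, {"CASP3"}, params)
print(f"BPS={scores.bps:.4f}  MFS={scores.mfs}  CCS={scores.ccs}  GOS={scores.gos:.4f}")
# One annotation at the leaf contributes 1.0 there, 0.5 one level up and
# 0.25 at the root: BPS = GOS = 1.75 for this single-namespace chain.
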