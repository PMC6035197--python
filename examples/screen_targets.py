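"""Classify drug-target candidates from two evidence streams.

A target backed by both literature mining and pharmacophore mapping is
*primary*; in the default mode, literature-only targets are *secondary*
and pharmacophore-only targets *predicted*.
"""

from netpharm import TargetEvidence, apply_pharmacophore_threshold, screen_targets
from netpharm.screening import merge_evidence

literature = [TargetEvidence(t, in_literature=True) for t in ("CASP3", "TGFB2", "IL2")]
pharmacophore = [
    TargetEvidence(t, in_pharmacophore=True, pharmacophore_fit=fit)
    for t, fit in (("CASP3", 62.0), ("BRAF", 41.0), ("VDR", 24.0))
]

# fit threshold 30 (inclusive): VDR at 24 loses its pharmacophore support
pharmacophore = apply_pharmacophore_threshold(pharmacophore, min_fit=30)
screened = screen_targets(merge_evidence(literature, pharmacophore))

for s in sorted(screened, key=lambda s: (s.klass, s.target_id)):
    print(f"{s.target_id:8s} {s.klass}")
# CASP3 is primary (both streams agree); TGFB2/IL2 are literature-only
# secondaries; BRAF is a pharmacophore-only prediction awaiting validation.
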