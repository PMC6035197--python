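"""Target screening from two evidence streams.

A candidate target may be supported by literature mining (LM), by
pharmacophore mapping (PMR), or both. Targets with both kinds of support
are *primary*; the classification of single-stream targets differs between
the two published readings of the screening rule, so it is selected by a
``mode`` flag:

``eq1`` (default)
    LM-only targets are *secondary*; PMR-only targets are *predicted*
    (computational support with no literature confirmation).
``results_text``
    PMR-only targets are *secondary*; LM-only targets have no direct
    in-silico interaction evidence, are flagged unsupported and excluded
    with a warning.
"""

from __future__ import annotations

import warnings
from typing import List

from .errors import ValidationError
from .types import ScreenedTarget, TargetEvidence

MODES = ("eq1", "results_text")

PRIMARY = "primary"
SECONDARY = "secondary"
PREDICTED = "predicted"


def screen_targets(
    evidence: List[TargetEvidence], mode: str = "eq1"
) -> List[ScreenedTarget]:
    """Classify each evidence record into primary/secondary/predicted.

    Input ids must be unique (merge duplicates upstream). Records with
    neither flag set raise :class:`ValidationError`.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    seen = set()
    for ev in evidence:
        if ev.target_id in seen:
            raise ValidationError(f"duplicate evidence id {ev.target_id!r}")
        seen.add(ev.target_id)

    out = []
    for ev in evidence:
        lm, pmr = ev.in_literature, ev.in_pharmacophore
        if not (lm or pmr):
            raise ValidationError(
                f"target {ev.target_id!r}: no evidence stream set"
            )
        if lm and pmr:
            klass = PRIMARY
        elif mode == "eq1":
            klass = SECONDARY if lm else PREDICTED
        else:  # results_text reading
            if pmr:
                klass = SECONDARY
            else:
                warnings.warn(
                    f"target {ev.target_id!r}: literature-only evidence is "
                    "unsupported in results_text mode; excluded",
                    stacklevel=2,
                )
                continue
        out.append(ScreenedTarget(ev.target_id, klass, ev))
    return out


def apply_pharmacophore_threshold(
    evidence: List[TargetEvidence],
    min_fit: float = 30.0,
    max_reserved: int = 300,
) -> List[TargetEvidence]:
    """Apply the pharmacophore fit-score threshold and reserve cap.

    Records whose fit score falls below ``min_fit`` (boundary inclusive:
    ``fit >= min_fit`` is retained) lose their pharmacophore flag; records
    with no fit score are treated as failing any positive threshold. At
    most ``max_reserved`` pharmacophore records are kept, highest fit
    first (ties broken lexicographically by target id); the rest lose the
    flag as well. Records left with no evidence at all are dropped.
    """
    if min_fit < 0:
        raise ValueError("min_fit must be nonnegative")
    if max_reserved < 1:
        raise ValueError("max_reserved must be positive")

    def passes(ev: TargetEvidence) -> bool:
        if not ev.in_pharmacophore:
            return False
        fit = ev.pharmacophore_fit
        if fit is None:
            return min_fit == 0
        return fit >= min_fit

    kept = sorted(
        (ev for ev in evidence if passes(ev)),
        key=lambda ev: (-(ev.pharmacophore_fit or 0.0), ev.target_id),
    )
    reserved = {ev.target_id for ev in kept[:max_reserved]}

    out = []
    for ev in evidence:
        if ev.in_pharmacophore and ev.target_id not in reserved:
            if not ev.in_literature:
                continue  # no evidence left
            ev = TargetEvidence(
                target_id=ev.target_id,
                in_literature=True,
                in_pharmacophore=False,
                pharmacophore_fit=ev.pharmacophore_fit,
                source_note=ev.source_note,
            )
        out.append(ev)
    return out


def merge_evidence(
    literature: List[TargetEvidence], pharmacophore: List[TargetEvidence]
) -> List[TargetEvidence]:
    """Merge two single-stream record lists into one record per target id."""
    merged: dict = {}
    for ev in list(literature) + list(pharmacophore):
        if ev.target_id not in merged:
            merged[ev.target_id] = ev
            continue
        old = merged[ev.target_id]
        fits = [f for f in (old.pharmacophore_fit, ev.pharmacophore_fit) if f is not None]
        merged[ev.target_id] = TargetEvidence(
            target_id=ev.target_id,
            in_literature=old.in_literature or ev.in_literature,
            in_pharmacophore=old.in_pharmacophore or ev.in_pharmacophore,
            pharmacophore_fit=max(fits) if fits else None,
            source_note="; ".join(s for s in (old.source_note, ev.source_note) if s),
        )
    return list(merged.values())
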