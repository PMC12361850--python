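"""Character-level majority voting over several systems' annotation sets.

Because the evaluation metric is defined per character, the natural voting
unit is the character: each system casts one vote per character position
(its linked concept, or "no annotation" where it predicts nothing), and a
concept is kept only where a strict majority of systems agree on it.
Ties and sub-quorum pluralities abstain.  Maximal runs of an identical
winning concept are then re-assembled into spans, which by construction
cannot overlap.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import AnnotationSet, SpanAnnotation

__all__ = ["VoteConfig", "majority_vote"]


@dataclass(frozen=True)
class VoteConfig:
    """Voting rule: quorum defaults to a strict majority of the systems."""

    quorum: int | None = None  # None -> floor(n/2) + 1
    source_id: str = "vote"

    def resolve_quorum(self, n_systems: int) -> int:
        quorum = self.quorum if self.quorum is not None else n_systems // 2 + 1
        if quorum <= n_systems / 2:
            raise ValueError(
                f"quorum {quorum} is not a strict majority of {n_systems} systems"
            )
        return quorum


def majority_vote(
    preds: Sequence[AnnotationSet], config: VoteConfig = VoteConfig()
) -> AnnotationSet:
    """Combine prediction sets by strict per-character majority.

    A character is annotated with concept c in the output iff at least
    ``quorum`` systems annotate it with c (systems predicting nothing there
    still count in the denominator).  The result is independent of the
    order of ``preds``, and voting over k copies of one set returns that
    set.
    """
    preds = list(preds)
    if len(preds) < 2:
        raise ValueError("majority voting needs at least 2 systems")
    quorum = config.resolve_quorum(len(preds))

    votes: dict[str, dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    for aset in preds:
        for ann in aset:
            per_doc = votes[ann.doc_id]
            for pos in range(ann.start, ann.end):
                per_doc[pos][ann.concept_id] += 1

    out: list[SpanAnnotation] = []
    for doc_id in sorted(votes):
        per_doc = votes[doc_id]
        winners: dict[int, str] = {}
        for pos, tally in per_doc.items():
            (concept, count), = tally.most_common(1)
            if count >= quorum:  # strict majority; ties cannot reach quorum twice
                winners[pos] = concept
        run_start: int | None = None
        run_concept: str | None = None
        prev_pos: int | None = None
        for pos in sorted(winners):
            concept = winners[pos]
            if run_start is not None and pos == prev_pos + 1 and concept == run_concept:
                prev_pos = pos
                continue
            if run_start is not None:
                out.append(SpanAnnotation(doc_id, run_start, prev_pos + 1, run_concept,
                                          config.source_id))
            run_start, run_concept, prev_pos = pos, concept, pos
        if run_start is not None:
            out.append(SpanAnnotation(doc_id, run_start, prev_pos + 1, run_concept,
                                      config.source_id))
    return AnnotationSet(config.source_id, out)
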