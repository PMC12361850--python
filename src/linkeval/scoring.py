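"""Character-level IoU scoring for entity-linking submissions.

The evaluation asks whether a system found the same characters AND linked
them to the same concept as the ground truth.  For a concept c, with G_c the
set of (document, position) pairs the gold standard links to c and P_c the
set the system links to c,

    IoU_c = |P_c ∩ G_c| / (|P_c| + |G_c| - |P_c ∩ G_c|)

i.e. the Jaccard similarity of the two character sets, and the submission
score is the unweighted mean of IoU_c over all concepts appearing in either
the gold standard or the prediction.  A hallucinated concept (predicted,
never gold) therefore enters the mean with IoU 0, and over-long spans are
penalized through the union in the denominator.

IoU_c relates to character-level precision (|∩|/|P_c|) and recall
(|∩|/|G_c|) through the identity

    IoU_c = P·R / (P + R - P·R).

The class-weighted variant weights each concept's IoU by its number of
ground-truth annotation instances, so frequent concepts dominate; comparing
the two aggregates shows whether rare concepts are disproportionately hard.

Internally all set sizes are computed by sorted-interval sweeps; character
sets are never materialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import AnnotationSet, SpanAnnotation

__all__ = [
    "CharAssignment",
    "ConceptScore",
    "ScoreReport",
    "char_assignment",
    "concept_iou",
    "concept_precision_recall",
    "score_submission",
    "bootstrap_ci",
    "iaa_jaccard",
]


class CharAssignment:
    """The per-character concept assignment derived from one annotation set.

    Position i of document d is assigned concept c iff some annotation
    [start, end) with concept c covers i; the no-overlap invariant of
    :class:`AnnotationSet` guarantees at most one concept per position.
    Stored as sorted disjoint intervals per (concept, document).
    """

    def __init__(self, aset: AnnotationSet) -> None:
        self.source_id = aset.source_id
        self._intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}
        self._n_chars: dict[str, int] = {}
        for ann in aset:
            per_doc = self._intervals.setdefault(ann.concept_id, {})
            per_doc.setdefault(ann.doc_id, []).append((ann.start, ann.end))
            self._n_chars[ann.concept_id] = self._n_chars.get(ann.concept_id, 0) + len(ann)
        for per_doc in self._intervals.values():
            for ivs in per_doc.values():
                ivs.sort()

    @property
    def concept_ids(self) -> set[str]:
        return set(self._intervals)

    def n_chars(self, concept_id: str) -> int:
        """Total characters assigned to the concept across all documents."""
        return self._n_chars.get(concept_id, 0)

    @property
    def total_chars(self) -> int:
        return sum(self._n_chars.values())

    def intervals(self, concept_id: str) -> Mapping[str, list[tuple[int, int]]]:
        return self._intervals.get(concept_id, {})

    def concept_at(self, doc_id: str, position: int) -> str | None:
        """Concept assigned at one character position, or None (O(spans) probe)."""
        for concept_id, per_doc in self._intervals.items():
            for start, end in per_doc.get(doc_id, ()):
                if start <= position < end:
                    return concept_id
        return None


def char_assignment(aset: AnnotationSet) -> CharAssignment:
    """Derive the per-character concept assignment of an annotation set."""
    return CharAssignment(aset)


def _intersect_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Total overlap of two sorted lists of disjoint half-open intervals."""
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _concept_counts(
    gt: CharAssignment, pred: CharAssignment, concept_id: str
) -> tuple[int, int, int]:
    """(|G_c|, |P_c|, |G_c ∩ P_c|) character counts for one concept."""
    n_gt = gt.n_chars(concept_id)
    n_pred = pred.n_chars(concept_id)
    gt_ivs = gt.intervals(concept_id)
    pred_ivs = pred.intervals(concept_id)
    n_int = sum(
        _intersect_length(gt_ivs[doc_id], pred_ivs[doc_id])
        for doc_id in gt_ivs.keys() & pred_ivs.keys()
    )
    return n_gt, n_pred, n_int


def concept_iou(gt: CharAssignment, pred: CharAssignment, concept_id: str) -> float:
    """Character-level IoU for one concept: |∩| / (|P| + |G| − |∩|)."""
    n_gt, n_pred, n_int = _concept_counts(gt, pred, concept_id)
    if n_gt == 0 and n_pred == 0:
        raise ValueError(f"concept {concept_id!r} appears in neither assignment")
    return n_int / (n_gt + n_pred - n_int)


def concept_precision_recall(
    gt: CharAssignment, pred: CharAssignment, concept_id: str
) -> tuple[float, float]:
    """Character-level (precision, recall) for one concept.

    Precision is ``nan`` when the concept is never predicted, recall ``nan``
    when it never occurs in the gold standard; both zero counts raise.
    """
    n_gt, n_pred, n_int = _concept_counts(gt, pred, concept_id)
    if n_gt == 0 and n_pred == 0:
        raise ValueError(f"concept {concept_id!r} appears in neither assignment")
    precision = n_int / n_pred if n_pred else float("nan")
    recall = n_int / n_gt if n_gt else float("nan")
    return precision, recall


@dataclass(frozen=True)
class ConceptScore:
    """Per-concept character counts and derived IoU / precision / recall."""

    concept_id: str
    iou: float
    precision: float
    recall: float
    n_gt_chars: int
    n_pred_chars: int
    n_intersect_chars: int
    n_gt_instances: int


@dataclass
class ScoreReport:
    """Per-concept scores plus mean and class-weighted aggregates.

    ``n_concepts`` is the averaging denominator: the number of concepts in
    the union of gold and predicted concept inventories.  Bootstrap CI
    fields are populated by :func:`bootstrap_ci`.
    """

    source_id: str
    per_concept: dict[str, ConceptScore]
    mean_iou: float
    weighted_iou: float
    n_concepts: int
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def iou_of(self, concept_id: str, default: float = 0.0) -> float:
        score = self.per_concept.get(concept_id)
        return score.iou if score is not None else default


def score_submission(gt: AnnotationSet, pred: AnnotationSet) -> ScoreReport:
    """Score a prediction set against the gold standard.

    One :class:`ConceptScore` per concept in the union of the two concept
    inventories; the mean averages over exactly that union, the weighted
    mean weights by gold instance counts (hallucinated concepts get weight
    zero but still drag the unweighted mean down).
    """
    if gt.doc_ids and pred.doc_ids and not (gt.doc_ids & pred.doc_ids):
        warnings.warn(
            f"gold ({gt.source_id!r}) and prediction ({pred.source_id!r}) share no "
            "documents; all scores will be zero",
            stacklevel=2,
        )
    gt_chars = char_assignment(gt)
    pred_chars = char_assignment(pred)
    concepts = sorted(gt_chars.concept_ids | pred_chars.concept_ids)
    per_concept: dict[str, ConceptScore] = {}
    for cid in concepts:
        n_gt, n_pred, n_int = _concept_counts(gt_chars, pred_chars, cid)
        iou = n_int / (n_gt + n_pred - n_int)
        per_concept[cid] = ConceptScore(
            concept_id=cid,
            iou=iou,
            precision=n_int / n_pred if n_pred else float("nan"),
            recall=n_int / n_gt if n_gt else float("nan"),
            n_gt_chars=n_gt,
            n_pred_chars=n_pred,
            n_intersect_chars=n_int,
            n_gt_instances=len(gt.for_concept(cid)),
        )
    n = len(concepts)
    mean_iou = sum(s.iou for s in per_concept.values()) / n if n else float("nan")
    total_instances = sum(s.n_gt_instances for s in per_concept.values())
    if total_instances:
        weighted_iou = (
            sum(s.iou * s.n_gt_instances for s in per_concept.values()) / total_instances
        )
    else:
        weighted_iou = float("nan")
    return ScoreReport(
        source_id=pred.source_id,
        per_concept=per_concept,
        mean_iou=mean_iou,
        weighted_iou=weighted_iou,
        n_concepts=n,
    )


def bootstrap_ci(
    report: ScoreReport,
    n_boot: int = 1000,
    seed: int = 0,
    weighted: bool = False,
) -> tuple[float, float]:
    """Percentile 95% CI of the (weighted) mean IoU by resampling concepts.

    Per-concept IoU values are resampled with replacement ``n_boot`` times;
    the interval is the 2.5/97.5 percentile of the resampled mean.  For the
    weighted mean, a concept's gold instance count travels with it and the
    weights are renormalized within each replicate.  Returns ``(low, high)``
    and stores them on the report.
    """
    scores = list(report.per_concept.values())
    if not scores:
        raise ValueError("cannot bootstrap an empty report")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(scores) == 1 and not weighted:
        warnings.warn("single-concept report: bootstrap interval is degenerate", stacklevel=2)
    ious = np.array([s.iou for s in scores])
    weights = np.array([s.n_gt_instances for s in scores], dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(scores), size=(n_boot, len(scores)))
    if weighted:
        w = weights[idx]
        stats = (ious[idx] * w).sum(axis=1) / w.sum(axis=1)
    else:
        stats = ious[idx].mean(axis=1)
    low, high = np.percentile(stats, [2.5, 97.5])
    report.ci_low, report.ci_high = float(low), float(high)
    report.n_boot, report.seed = n_boot, seed
    return float(low), float(high)


def iaa_jaccard(a: AnnotationSet, b: AnnotationSet) -> float:
    """Inter-annotator agreement as an instance-level Jaccard score.

    Two annotations match when they are in the same document, their spans
    overlap, and they link to the same concept — boundary variation is
    deliberately ignored.  Matches are made one-to-one greedily, largest
    character overlap first (ties: earlier start, then ``a``'s order), and
    the score is |M| / (|a| + |b| − |M|).  Two identical sets score 1.
    """
    if len(a) == 0 and len(b) == 0:
        return 1.0
    candidates: list[tuple[int, int, int, int, int]] = []
    b_by_doc: dict[str, list[tuple[int, SpanAnnotation]]] = {}
    for j, ann in enumerate(b):
        b_by_doc.setdefault(ann.doc_id, []).append((j, ann))
    for i, ann_a in enumerate(a):
        for j, ann_b in b_by_doc.get(ann_a.doc_id, ()):
            if ann_a.concept_id == ann_b.concept_id and ann_a.overlaps(ann_b):
                overlap = min(ann_a.end, ann_b.end) - max(ann_a.start, ann_b.start)
                candidates.append((-overlap, min(ann_a.start, ann_b.start), i, j, overlap))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    n_match = 0
    for _neg, _start, i, j, _ov in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n_match += 1
    return n_match / (len(a) + len(b) - n_match)
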