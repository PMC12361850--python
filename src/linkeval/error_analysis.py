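"""Error taxonomy for span+link predictions, difficulty partition, rank reports.

Every gold/predicted annotation pair in the same document either overlaps or
not, and overlapping pairs either agree on the concept or not.  That yields
five mutually exclusive record categories:

* Correct — overlapping pair, same concept;
* False-Negative Link / False-Positive Link — overlapping pair, different
  concepts (one linker mistake produces both records, charged to the gold
  and the predicted concept respectively);
* False-Negative Span — a gold annotation overlapping no prediction (the
  recognizer missed the entity);
* False-Positive Span — a prediction overlapping no gold annotation (the
  recognizer hallucinated an entity).

Each record is weighted by its own annotation's span length in characters,
so the category table reports shares of affected characters, not of
annotation counts.  A gold annotation overlapped by k predictions yields k
pairwise records (pass ``dedupe=True`` to keep only the best record per
annotation).
"""

from __future__ import annotations

import enum
import warnings
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .corpus import AnnotationSet, SpanAnnotation

__all__ = [
    "ErrorCategory",
    "ErrorRecord",
    "ErrorLedger",
    "DifficultyPartition",
    "classify_errors",
    "error_table",
    "partition_hard_easy",
    "feature_associations",
    "system_correlation",
]


class ErrorCategory(str, enum.Enum):
    CORRECT = "Correct"
    FP_LINK = "False-Positive Link"
    FP_SPAN = "False-Positive Span"
    FN_LINK = "False-Negative Link"
    FN_SPAN = "False-Negative Span"


#: Column order used by the category table.
CATEGORY_ORDER = [
    ErrorCategory.CORRECT,
    ErrorCategory.FP_LINK,
    ErrorCategory.FP_SPAN,
    ErrorCategory.FN_LINK,
    ErrorCategory.FN_SPAN,
]

#: Categories whose records are derived from a gold annotation.
GOLD_SIDE = {ErrorCategory.CORRECT, ErrorCategory.FN_LINK, ErrorCategory.FN_SPAN}


@dataclass(frozen=True)
class ErrorRecord:
    annotation: SpanAnnotation
    category: ErrorCategory

    @property
    def char_weight(self) -> int:
        return len(self.annotation)

    @property
    def concept_id(self) -> str:
        return self.annotation.concept_id


class ErrorLedger:
    """The records produced by :func:`classify_errors`, with aggregation views."""

    def __init__(self, records: Iterable[ErrorRecord]) -> None:
        self.records: tuple[ErrorRecord, ...] = tuple(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def char_weight_by_category(self) -> dict[ErrorCategory, int]:
        weights = {cat: 0 for cat in CATEGORY_ORDER}
        for rec in self.records:
            weights[rec.category] += rec.char_weight
        return weights

    def char_weight_by_concept(self) -> dict[str, dict[ErrorCategory, int]]:
        out: dict[str, dict[ErrorCategory, int]] = defaultdict(
            lambda: {cat: 0 for cat in CATEGORY_ORDER}
        )
        for rec in self.records:
            out[rec.concept_id][rec.category] += rec.char_weight
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "doc_id": [r.annotation.doc_id for r in self.records],
                "start": [r.annotation.start for r in self.records],
                "end": [r.annotation.end for r in self.records],
                "concept_id": [r.concept_id for r in self.records],
                "source_id": [r.annotation.source_id for r in self.records],
                "category": [r.category.value for r in self.records],
                "char_weight": [r.char_weight for r in self.records],
            }
        )


def _overlapping(
    ann: SpanAnnotation,
    starts: Sequence[int],
    anns: Sequence[SpanAnnotation],
) -> list[SpanAnnotation]:
    """Annotations in a start-sorted per-document list overlapping ``ann``.

    The list may contain overlapping spans (a bag union across systems), so
    scan left from the bisection point until starts fall behind the longest
    plausible reach; span lengths are bounded in practice, a plain linear
    scan left is fine at ledger scale.
    """
    out = []
    i = bisect_left(starts, ann.end)  # anns[i:] start at/after ann.end: no overlap
    for k in range(i - 1, -1, -1):
        cand = anns[k]
        if cand.end > ann.start:
            out.append(cand)
        # cannot break early: earlier-starting spans may still reach past ann.start
    out.reverse()
    return out


def classify_errors(
    gt: AnnotationSet,
    preds: AnnotationSet | Iterable[AnnotationSet],
    dedupe: bool = False,
) -> ErrorLedger:
    """Assign every annotation to the five-way error taxonomy.

    ``preds`` may be one prediction set or several; several are treated as a
    bag union (duplicates across systems preserved).  With ``dedupe=True``
    each gold annotation contributes at most one record (Correct preferred
    over link errors) and each prediction at most one.
    """
    if isinstance(preds, AnnotationSet):
        pred_sets = [preds]
    else:
        pred_sets = list(preds)
    pred_bag: list[SpanAnnotation] = [ann for aset in pred_sets for ann in aset]

    pred_by_doc: dict[str, list[SpanAnnotation]] = defaultdict(list)
    for ann in pred_bag:
        pred_by_doc[ann.doc_id].append(ann)
    for anns in pred_by_doc.values():
        anns.sort(key=lambda a: (a.start, a.end))
    pred_starts = {doc: [a.start for a in anns] for doc, anns in pred_by_doc.items()}

    gt_by_doc: dict[str, list[SpanAnnotation]] = defaultdict(list)
    for ann in gt:
        gt_by_doc[ann.doc_id].append(ann)
    gt_starts = {doc: [a.start for a in anns] for doc, anns in gt_by_doc.items()}

    records: list[ErrorRecord] = []
    for g in gt:
        overlapping = _overlapping(
            g, pred_starts.get(g.doc_id, ()), pred_by_doc.get(g.doc_id, ())
        )
        if not overlapping:
            records.append(ErrorRecord(g, ErrorCategory.FN_SPAN))
            continue
        if dedupe:
            if any(s.concept_id == g.concept_id for s in overlapping):
                records.append(ErrorRecord(g, ErrorCategory.CORRECT))
            else:
                records.append(ErrorRecord(g, ErrorCategory.FN_LINK))
            continue
        for s in overlapping:
            if s.concept_id == g.concept_id:
                records.append(ErrorRecord(g, ErrorCategory.CORRECT))
            else:
                records.append(ErrorRecord(g, ErrorCategory.FN_LINK))
                records.append(ErrorRecord(s, ErrorCategory.FP_LINK))
    for s in pred_bag:
        overlapping = _overlapping(s, gt_starts.get(s.doc_id, ()), gt_by_doc.get(s.doc_id, ()))
        if not overlapping:
            records.append(ErrorRecord(s, ErrorCategory.FP_SPAN))
        elif dedupe and not any(g.concept_id == s.concept_id for g in overlapping):
            records.append(ErrorRecord(s, ErrorCategory.FP_LINK))
    return ErrorLedger(records)


@dataclass(frozen=True)
class DifficultyPartition:
    """Hard/easy split of the scored concepts at an IoU threshold."""

    hard: frozenset[str]
    easy: frozenset[str]
    threshold: float

    def class_of(self, concept_id: str) -> str | None:
        if concept_id in self.hard:
            return "hard"
        if concept_id in self.easy:
            return "easy"
        return None


def partition_hard_easy(reports, threshold: float = 0.1) -> DifficultyPartition:
    """Split concepts into hard (IoU < threshold in EVERY report) and easy.

    A concept absent from a report counts as IoU 0 there.  The universe is
    the union of concepts across reports.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one score report")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    concepts: set[str] = set()
    for rep in reports:
        concepts.update(rep.per_concept)
    hard = {
        cid for cid in concepts if all(rep.iou_of(cid, 0.0) < threshold for rep in reports)
    }
    return DifficultyPartition(
        hard=frozenset(hard), easy=frozenset(concepts - hard), threshold=threshold
    )


def error_table(ledger: ErrorLedger, partition: DifficultyPartition) -> pd.DataFrame:
    """Character-weight percentage of each error category per difficulty class.

    Rows "hard"/"easy", columns the five categories; each row is normalized
    within its class and sums to 100.  Records whose concept falls in
    neither class (never scored) are dropped; an empty class yields NaNs.
    """
    if len(ledger) == 0:
        raise ValueError("empty error ledger")
    totals = {
        cls: {cat: 0 for cat in CATEGORY_ORDER} for cls in ("hard", "easy")
    }
    for rec in ledger:
        cls = partition.class_of(rec.concept_id)
        if cls is not None:
            totals[cls][rec.category] += rec.char_weight
    rows = {}
    for cls, weights in totals.items():
        grand = sum(weights.values())
        if grand == 0:
            rows[cls] = {cat.value: float("nan") for cat in CATEGORY_ORDER}
        else:
            rows[cls] = {cat.value: 100.0 * weights[cat] / grand for cat in CATEGORY_ORDER}
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        ["hard", "easy"], [cat.value for cat in CATEGORY_ORDER]
    ]


def feature_associations(report, features: pd.DataFrame) -> pd.Series:
    """Kendall tau-b between per-concept IoU and each difficulty feature.

    ``features`` is a frame indexed by concept id (as produced by
    :func:`linkeval.concept_features.feature_table`); only numeric columns
    with at least 3 concepts in common with the report are correlated.
    Constant columns yield NaN.
    """
    ious = pd.Series({cid: s.iou for cid, s in report.per_concept.items()}, name="iou")
    common = features.index.intersection(ious.index)
    if len(common) < 3:
        raise ValueError("need at least 3 concepts in common")
    out = {}
    y = ious.loc[common]
    for col in features.columns:
        if not pd.api.types.is_numeric_dtype(features[col]):
            continue
        x = features.loc[common, col]
        mask = x.notna() & y.notna()
        if mask.sum() < 3 or x[mask].nunique() <= 1 or y[mask].nunique() <= 1:
            out[col] = float("nan")
            continue
        tau, _ = stats.kendalltau(x[mask], y[mask])
        out[col] = float(tau)
    return pd.Series(out, name="kendall_tau")


def system_correlation(report_a, report_b) -> float:
    """Spearman rank correlation of per-concept IoUs between two systems.

    Computed over the union of the two concept inventories; a concept a
    system never scored counts as IoU 0 for it.  A constant score vector
    leaves the rank correlation undefined: flagged with a warning, NaN.
    """
    concepts = sorted(set(report_a.per_concept) | set(report_b.per_concept))
    if len(concepts) < 3:
        raise ValueError("need at least 3 concepts in common")
    a = [report_a.iou_of(c, 0.0) for c in concepts]
    b = [report_b.iou_of(c, 0.0) for c in concepts]
    if len(set(a)) <= 1 or len(set(b)) <= 1:
        warnings.warn(
            f"constant score vector between {report_a.source_id!r} and "
            f"{report_b.source_id!r}: rank correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
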