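"""Independent brute-force re-implementations used as test oracles.

Everything here works by explicitly materializing character sets or by
naive double loops — deliberately different routes from the interval-sweep
implementations under test.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from linkeval.corpus import AnnotationSet, Corpus, Document, SpanAnnotation


def char_sets(aset: AnnotationSet) -> dict[str, set[tuple[str, int]]]:
    """concept -> explicit set of (doc_id, position) pairs."""
    sets: dict[str, set[tuple[str, int]]] = defaultdict(set)
    for ann in aset:
        for i in range(ann.start, ann.end):
            sets[ann.concept_id].add((ann.doc_id, i))
    return dict(sets)


def brute_iou(gt: AnnotationSet, pred: AnnotationSet, concept_id: str) -> float:
    g = char_sets(gt).get(concept_id, set())
    p = char_sets(pred).get(concept_id, set())
    union = g | p
    return len(g & p) / len(union) if union else float("nan")


def brute_precision_recall(gt: AnnotationSet, pred: AnnotationSet, concept_id: str):
    g = char_sets(gt).get(concept_id, set())
    p = char_sets(pred).get(concept_id, set())
    inter = len(g & p)
    return (inter / len(p) if p else float("nan"), inter / len(g) if g else float("nan"))


def brute_error_categories(gt: AnnotationSet, pred_bag: list[SpanAnnotation]) -> Counter:
    """Multiset of (doc, start, end, concept, category) via naive double loops."""

    def overlaps(a, b):
        return a.doc_id == b.doc_id and a.start < b.end and b.start < a.end

    results: Counter = Counter()

    def add(ann, category):
        results[(ann.doc_id, ann.start, ann.end, ann.concept_id, category)] += 1

    for g in gt:
        matched = False
        for s in pred_bag:
            if overlaps(g, s):
                matched = True
                if g.concept_id == s.concept_id:
                    add(g, "Correct")
                else:
                    add(g, "False-Negative Link")
                    add(s, "False-Positive Link")
        if not matched:
            add(g, "False-Negative Span")
    for s in pred_bag:
        if not any(overlaps(s, g) for g in gt):
            add(s, "False-Positive Span")
    return results


def brute_vote(preds: list[AnnotationSet]) -> dict[tuple[str, int], str]:
    """Per-character strict-majority winner via explicit tallies."""
    quorum = len(preds) // 2 + 1
    tallies: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for aset in preds:
        for ann in aset:
            for i in range(ann.start, ann.end):
                tallies[(ann.doc_id, i)][ann.concept_id] += 1
    winners = {}
    for key, tally in tallies.items():
        concept, count = tally.most_common(1)[0]
        if count >= quorum:
            winners[key] = concept
    return winners


def random_case(
    rng: np.random.Generator,
    n_docs: int = 3,
    doc_len: int = 120,
    n_concepts: int = 5,
    max_spans_per_doc: int = 6,
    min_spans_per_doc: int = 0,
) -> tuple[Corpus, AnnotationSet, AnnotationSet]:
    """A tiny random corpus with independent gold and prediction sets.

    Spans within each set are non-overlapping; across the two sets they
    overlap freely, so all five error categories and partial-overlap IoUs
    are exercised.
    """
    concepts = [f"c{k}" for k in range(n_concepts)]
    docs = [Document(f"d{j}", "x" * int(rng.integers(20, doc_len))) for j in range(n_docs)]

    def random_set(source: str) -> AnnotationSet:
        anns = []
        for doc in docs:
            n = int(rng.integers(min_spans_per_doc, max_spans_per_doc + 1))
            cuts = sorted(rng.choice(len(doc.text) + 1, size=min(2 * n, len(doc.text) + 1),
                                     replace=False))
            for a, b in zip(cuts[::2], cuts[1::2]):
                if a < b:
                    concept = concepts[int(rng.integers(n_concepts))]
                    anns.append(SpanAnnotation(doc.doc_id, int(a), int(b), concept, source))
        return AnnotationSet(source, anns)

    return Corpus(docs), random_set("gold"), random_set("pred")
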