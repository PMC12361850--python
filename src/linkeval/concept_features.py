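"""Concept-level difficulty features for entity linking.

For each concept the table carries:

* ``mean_span_length`` — mean character length of its annotated spans;
* ``concept_entropy`` — Shannon entropy (bits) of the bag of distinct
  surface strings linked to the concept: how many different ways the
  concept is written;
* ``annotation_entropy`` — entropy (bits) of the bag of concepts that the
  concept's surface strings are linked to anywhere in the corpus: how
  ambiguous those strings are as linking targets.  A concept whose spans
  are also common spans of many other concepts gets a high value;
* ``depth`` — shortest is-a distance to the terminology root, in edges;
* ``n_examples`` — number of training-split annotations;
* ``n_notes`` — number of distinct training documents containing it.

Surface strings are normalized (lowercase, trimmed, internal whitespace
collapsed) before bagging so trivial casing/spacing variants do not inflate
the entropies.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import AnnotationSet, Corpus, Terminology, ValidationError, extract_span_text

__all__ = [
    "SpanIndex",
    "normalize_span",
    "build_span_index",
    "concept_entropy",
    "annotation_entropy",
    "concept_depth",
    "feature_table",
]

_WS = re.compile(r"\s+")


def normalize_span(text: str) -> str:
    """Default surface-string normalization: lowercase, trim, collapse whitespace."""
    return _WS.sub(" ", text.strip()).lower()


@dataclass
class SpanIndex:
    """Bidirectional bag index between concepts and normalized span strings.

    ``by_concept[c]`` counts surface strings annotated with concept c;
    ``by_span[t]`` counts concepts that surface string t is linked to.  The
    two views are exact transposes, each with total multiplicity equal to
    the number of indexed annotations.
    """

    by_concept: dict[str, Counter]
    by_span: dict[str, Counter]

    @property
    def n_annotations(self) -> int:
        return sum(sum(bag.values()) for bag in self.by_concept.values())


def build_span_index(
    sets: Iterable[AnnotationSet],
    docs: Corpus,
    normalizer: Callable[[str], str] = normalize_span,
) -> SpanIndex:
    """Index annotation sets into concept↔span-string bags."""
    by_concept: dict[str, Counter] = defaultdict(Counter)
    by_span: dict[str, Counter] = defaultdict(Counter)
    for aset in sets:
        for ann in aset:
            if ann.doc_id not in docs:
                raise ValidationError(f"annotation references unknown document {ann.doc_id!r}")
            text = normalizer(extract_span_text(docs[ann.doc_id], ann))
            by_concept[ann.concept_id][text] += 1
            by_span[text][ann.concept_id] += 1
    return SpanIndex(by_concept=dict(by_concept), by_span=dict(by_span))


def _entropy_bits(counts: Iterable[int]) -> float:
    return float(stats.entropy(np.asarray(list(counts), dtype=float), base=2))


def concept_entropy(index: SpanIndex, concept_id: str) -> float:
    """Entropy (bits) of the distribution of surface strings of one concept."""
    bag = index.by_concept.get(concept_id)
    if bag is None:
        raise ValueError(f"concept {concept_id!r} not in span index")
    return _entropy_bits(bag.values())


def annotation_entropy(
    index: SpanIndex, concept_id: str, weight_by_span_multiplicity: bool = False
) -> float:
    """Entropy (bits) of the concepts competing for one concept's surface strings.

    Aggregates, over the concept's distinct surface strings, the corpus-wide
    bag of concepts those strings are linked to.  By default each distinct
    string contributes its concept bag once; with
    ``weight_by_span_multiplicity=True`` it contributes once per occurrence
    under this concept.
    """
    bag = index.by_concept.get(concept_id)
    if bag is None:
        raise ValueError(f"concept {concept_id!r} not in span index")
    combined: Counter = Counter()
    for span_text, mult in bag.items():
        weight = mult if weight_by_span_multiplicity else 1
        for cid, count in index.by_span[span_text].items():
            combined[cid] += weight * count
    return _entropy_bits(combined.values())


def concept_depth(term: Terminology, concept_id: str) -> int:
    """Shortest is-a chain length (edges) from a concept to the root."""
    return term.depth(concept_id)


def feature_table(
    train: AnnotationSet,
    test: AnnotationSet,
    docs: Corpus,
    term: Terminology | None = None,
    normalizer: Callable[[str], str] = normalize_span,
) -> pd.DataFrame:
    """Difficulty-feature table, one row per concept observed in either split.

    Entropies and mean span length are computed over both splits pooled;
    ``n_examples`` and ``n_notes`` count the training split only, so a
    test-only concept has ``n_examples == 0`` yet fully defined entropies.
    Depth is NaN for concepts missing from the terminology (or when no
    terminology is given).
    """
    index = build_span_index([train, test], docs, normalizer)
    lengths: dict[str, list[int]] = defaultdict(list)
    for aset in (train, test):
        for ann in aset:
            lengths[ann.concept_id].append(len(ann))
    train_counts = Counter(ann.concept_id for ann in train)
    train_notes: dict[str, set[str]] = defaultdict(set)
    for ann in train:
        train_notes[ann.concept_id].add(ann.doc_id)

    rows = []
    for cid in sorted(index.by_concept):
        if term is not None and cid in term.concept_ids:
            depth: float = float(term.depth(cid))
        else:
            depth = float("nan")
        rows.append(
            {
                "concept_id": cid,
                "mean_span_length": float(np.mean(lengths[cid])),
                "concept_entropy": concept_entropy(index, cid),
                "annotation_entropy": annotation_entropy(index, cid),
                "depth": depth,
                "n_examples": train_counts.get(cid, 0),
                "n_notes": len(train_notes.get(cid, ())),
            }
        )
    return pd.DataFrame(rows).set_index("concept_id")
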