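"""Documents, span annotations, terminologies, and their exchange formats.

The exchange formats are deliberately small and text-based:

* annotations — CSV with columns ``note_id,start,end,concept_id`` (UTF-8,
  header mandatory);
* documents — a two-column CSV ``note_id,text`` or one plain-text file per
  note (filename = note id);
* terminology — two TSVs: a descriptions table ``concept_id<TAB>term`` and a
  relationships table ``child_id<TAB>parent_id``, emulating a snapshot subset
  of a clinical terminology such as SNOMED CT.

Character offsets are 0-based, half-open ``[start, end)`` and index the
decoded character sequence of the note, so span length equals
``end - start``.  Overlap means a non-empty intersection of half-open
intervals within the same document; annotation sets from a single source
must be overlap-free.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "ValidationError",
    "ParseError",
    "Document",
    "Corpus",
    "SpanAnnotation",
    "AnnotationSet",
    "Terminology",
    "extract_span_text",
    "read_annotations",
    "write_annotations",
    "read_documents",
    "write_documents",
    "read_terminology",
    "write_terminology",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (overlap, bad offsets, cycle...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class Document:
    """One clinical note: an identifier and its character sequence."""

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")

    def __len__(self) -> int:
        return len(self.text)


class Corpus:
    """A keyed collection of :class:`Document` with unique ids."""

    def __init__(self, documents: Iterable[Document] = ()) -> None:
        self._docs: dict[str, Document] = {}
        for doc in documents:
            if doc.doc_id in self._docs:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            self._docs[doc.doc_id] = doc

    def __getitem__(self, doc_id: str) -> Document:
        return self._docs[doc_id]

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs.values())

    def __len__(self) -> int:
        return len(self._docs)

    @property
    def doc_ids(self) -> list[str]:
        return list(self._docs)


@dataclass(frozen=True, order=True)
class SpanAnnotation:
    """One (document, character interval, concept) link.

    The atom of both ground truth and predictions.  Empty spans are
    rejected at construction: ``0 <= start < end`` always holds.
    """

    doc_id: str
    start: int
    end: int
    concept_id: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start offset {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted span [{self.start}, {self.end}) in {self.doc_id!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "SpanAnnotation") -> bool:
        """Non-empty intersection of half-open intervals in the same document."""
        return (
            self.doc_id == other.doc_id
            and self.start < other.end
            and other.start < self.end
        )


class AnnotationSet:
    """A validated collection of annotations from one source.

    Invariants: no two annotations from the same document overlap, and every
    annotation carries the set's ``source_id``.  Annotations whose
    ``source_id`` is empty are stamped with the set's on construction.
    """

    def __init__(self, source_id: str, annotations: Iterable[SpanAnnotation] = ()) -> None:
        self.source_id = source_id
        stamped = []
        for ann in annotations:
            if not ann.source_id:
                ann = SpanAnnotation(ann.doc_id, ann.start, ann.end, ann.concept_id, source_id)
            elif ann.source_id != source_id:
                raise ValidationError(
                    f"annotation source {ann.source_id!r} != set source {source_id!r}"
                )
            stamped.append(ann)
        self.annotations: tuple[SpanAnnotation, ...] = tuple(
            sorted(stamped, key=lambda a: (a.doc_id, a.start, a.end, a.concept_id))
        )
        self._by_doc: dict[str, list[SpanAnnotation]] = defaultdict(list)
        self._by_concept: dict[str, list[SpanAnnotation]] = defaultdict(list)
        for ann in self.annotations:
            self._by_doc[ann.doc_id].append(ann)
            self._by_concept[ann.concept_id].append(ann)
        for doc_id, anns in self._by_doc.items():
            for prev, cur in zip(anns, anns[1:]):
                if prev.overlaps(cur):
                    raise ValidationError(
                        f"overlapping annotations in {doc_id!r}: "
                        f"[{prev.start}, {prev.end}) {prev.concept_id} and "
                        f"[{cur.start}, {cur.end}) {cur.concept_id}"
                    )

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[SpanAnnotation]:
        return iter(self.annotations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.source_id == other.source_id and self.annotations == other.annotations

    def for_doc(self, doc_id: str) -> list[SpanAnnotation]:
        return list(self._by_doc.get(doc_id, ()))

    def for_concept(self, concept_id: str) -> list[SpanAnnotation]:
        return list(self._by_concept.get(concept_id, ()))

    @property
    def doc_ids(self) -> set[str]:
        return set(self._by_doc)

    @property
    def concept_ids(self) -> set[str]:
        return set(self._by_concept)

    def validate_against(self, corpus: Corpus) -> None:
        """Check every annotation's offsets lie within its document."""
        for ann in self.annotations:
            if ann.doc_id not in corpus:
                raise ValidationError(f"annotation references unknown document {ann.doc_id!r}")
            if ann.end > len(corpus[ann.doc_id]):
                raise ValidationError(
                    f"span [{ann.start}, {ann.end}) exceeds document "
                    f"{ann.doc_id!r} of length {len(corpus[ann.doc_id])}"
                )


def extract_span_text(doc: Document, ann: SpanAnnotation) -> str:
    """Return the substring of ``doc`` covered by the annotation's interval."""
    if ann.doc_id != doc.doc_id:
        raise ValidationError(f"annotation doc {ann.doc_id!r} != document {doc.doc_id!r}")
    if ann.end > len(doc.text):
        raise ValidationError(
            f"span end {ann.end} out of bounds for document of length {len(doc.text)}"
        )
    return doc.text[ann.start : ann.end]


# ---------------------------------------------------------------------------
# Annotation CSV exchange format


_ANN_COLUMNS = ["note_id", "start", "end", "concept_id"]


def read_annotations(path: str | Path, source_id: str) -> AnnotationSet:
    """Read an annotation CSV (``note_id,start,end,concept_id``) into a validated set."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header {_ANN_COLUMNS}") from None
        if [h.strip() for h in header] != _ANN_COLUMNS:
            raise ParseError(f"{path}:1: expected header {_ANN_COLUMNS}, got {header}")
        annotations = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            note_id, start_s, end_s, concept_id = row
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer offsets {start_s!r}, {end_s!r}"
                ) from None
            try:
                annotations.append(SpanAnnotation(note_id, start, end, concept_id, source_id))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return AnnotationSet(source_id, annotations)


def write_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write an annotation set to CSV; round-trips exactly through :func:`read_annotations`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANN_COLUMNS)
        for ann in aset:
            writer.writerow([ann.doc_id, ann.start, ann.end, ann.concept_id])


# ---------------------------------------------------------------------------
# Document exchange formats


def read_documents(path: str | Path) -> Corpus:
    """Read a corpus from a two-column CSV (``note_id,text``) or a directory of text files."""
    path = Path(path)
    docs: list[Document] = []
    if path.is_dir():
        for file in sorted(path.iterdir()):
            if file.is_file():
                docs.append(Document(file.stem, file.read_text(encoding="utf-8")))
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["note_id", "text"]:
                raise ParseError(f"{path}:1: expected header ['note_id', 'text'], got {header}")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
                docs.append(Document(row[0], row[1]))
    return Corpus(docs)


def write_documents(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as a two-column CSV ``note_id,text``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "text"])
        for doc in corpus:
            writer.writerow([doc.doc_id, doc.text])


# ---------------------------------------------------------------------------
# Terminology


@dataclass
class Terminology:
    """Concept identifiers, synonym sets, is-a edges, and a designated root.

    The is-a graph is a rooted multi-hierarchy: a directed acyclic graph in
    which every concept reaches the root along child→parent edges and a
    concept may have several parents.  ``depth`` is the shortest such path,
    in edges, with the root at depth 0.
    """

    concept_ids: set[str]
    synonyms: dict[str, list[str]]
    isa_edges: list[tuple[str, str]]
    root_id: str
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)
    _depths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.root_id not in self.concept_ids:
            raise ValidationError(f"root {self.root_id!r} not among concepts")
        for cid in self.concept_ids:
            if not self.synonyms.get(cid):
                raise ValidationError(f"concept {cid!r} has no synonyms")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.concept_ids)
        for child, parent in self.isa_edges:
            if child not in self.concept_ids or parent not in self.concept_ids:
                raise ValidationError(f"edge ({child!r}, {parent!r}) references unknown concept")
            graph.add_edge(child, parent)
        if graph.out_degree(self.root_id) > 0:
            raise ValidationError(f"root {self.root_id!r} must have no parent")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValidationError(f"is-a graph contains a cycle: {cycle}")
        self._graph = graph
        # single reverse BFS from the root gives every shortest child->parent depth
        self._depths = nx.single_source_shortest_path_length(graph.reverse(copy=False), self.root_id)

    def depth(self, concept_id: str) -> int:
        """Shortest child→parent distance from ``concept_id`` to the root, in edges."""
        if concept_id not in self.concept_ids:
            raise ValidationError(f"unknown concept {concept_id!r}")
        if concept_id not in self._depths:
            raise ValidationError(f"concept {concept_id!r} cannot reach root {self.root_id!r}")
        return self._depths[concept_id]

    def parents(self, concept_id: str) -> list[str]:
        return list(self._graph.successors(concept_id))

    def children(self, concept_id: str) -> list[str]:
        return list(self._graph.predecessors(concept_id))

    def siblings(self, concept_id: str) -> list[str]:
        """Concepts sharing at least one parent, excluding the concept itself."""
        sibs: set[str] = set()
        for parent in self.parents(concept_id):
            sibs.update(self.children(parent))
        sibs.discard(concept_id)
        return sorted(sibs)


def read_terminology(
    synonyms_path: str | Path, edges_path: str | Path, root_id: str
) -> Terminology:
    """Read a terminology from descriptions and relationships TSVs."""
    synonyms: dict[str, list[str]] = defaultdict(list)
    syn_path = Path(synonyms_path)
    with syn_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["concept_id", "term"]:
            raise ParseError(f"{syn_path}:1: expected header ['concept_id', 'term'], got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{syn_path}:{lineno}: expected 2 fields, got {len(row)}")
            synonyms[row[0]].append(row[1])
    edges: list[tuple[str, str]] = []
    edge_path = Path(edges_path)
    with edge_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["child_id", "parent_id"]:
            raise ParseError(
                f"{edge_path}:1: expected header ['child_id', 'parent_id'], got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{edge_path}:{lineno}: expected 2 fields, got {len(row)}")
            edges.append((row[0], row[1]))
    return Terminology(set(synonyms), dict(synonyms), edges, root_id)


def write_terminology(term: Terminology, synonyms_path: str | Path, edges_path: str | Path) -> None:
    """Write a terminology back to the two-TSV exchange format."""
    with Path(synonyms_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["concept_id", "term"])
        for cid in sorted(term.concept_ids):
            for syn in term.synonyms[cid]:
                writer.writerow([cid, syn])
    with Path(edges_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["child_id", "parent_id"])
        for child, parent in sorted(term.isa_edges):
            writer.writerow([child, parent])
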