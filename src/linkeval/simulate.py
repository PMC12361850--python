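"""Synthetic terminologies, corpora, gold annotations, and noisy predictions.

The generator emulates the statistical structure that makes clinical entity
linking hard, at desk scale and with no restricted data:

* a rooted is-a multi-hierarchy with synonym sets, where a configurable
  fraction of concepts have a second parent and a configurable fraction of
  surface strings are shared between two or more concepts (the many-to-many
  span↔concept ambiguity that drives annotation entropy);
* notes assembled from a fixed list of seven section headers with embedded
  synonym mentions separated by filler text, gold offsets exactly covering
  the mentions;
* heavy-tailed concept frequencies via a Zipf law over a random concept
  ranking, so a few concepts are common and most are rare;
* a four-channel prediction-noise process mirroring the span/link error
  taxonomy: missed gold spans (``p_miss`` → False-Negative Span), kept
  spans re-linked to a *sibling* concept (``p_confuse`` → False-Negative
  Link + False-Positive Link, concentrated among semantically adjacent
  concepts), boundary jitter (partial-overlap penalties), and spurious
  spans placed on unannotated text (``spur_rate`` per document →
  False-Positive Span), with every applied event recorded in a truth log.

Identical (config, seed) yields byte-identical bundles through the writers.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import (
    AnnotationSet,
    Corpus,
    Document,
    SpanAnnotation,
    Terminology,
    write_annotations,
    write_documents,
    write_terminology,
)

__all__ = [
    "NoiseConfig",
    "SimConfig",
    "SyntheticBundle",
    "gen_terminology",
    "gen_corpus",
    "perturb",
    "generate_bundle",
    "write_bundle",
    "estimate_noise_rates",
    "SECTION_HEADERS",
]

#: Fixed section skeleton of every synthetic note.
SECTION_HEADERS = [
    "Chief Complaint:",
    "History of Present Illness:",
    "Past Medical History:",
    "Physical Exam:",
    "Laboratory Results:",
    "Imaging:",
    "Discharge Disposition:",
]

_QUALIFIERS = [
    "acute", "chronic", "mild", "severe", "diffuse", "focal", "bilateral",
    "recurrent", "persistent", "transient", "progressive", "intermittent",
    "residual", "stable",
]
_SITES = [
    "hepatic", "renal", "cardiac", "pulmonary", "femoral", "cranial",
    "lumbar", "gastric", "splenic", "pleural", "pericardial", "cervical",
    "tibial", "aortic",
]
_FINDINGS = [
    "lesion", "fracture", "effusion", "edema", "stenosis", "infarct",
    "hemorrhage", "nodule", "mass", "thrombosis", "atrophy", "dilatation",
    "calcification", "inflammation",
]
_FILLER = [
    "patient", "denies", "reports", "noted", "on", "exam", "with", "no",
    "history", "of", "today", "unremarkable", "during", "admission",
    "course", "without", "follow", "up", "review", "prior",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel prediction noise, all channels independent.

    p_miss     probability a gold span is dropped entirely
    p_confuse  probability a kept span is re-linked to a sibling concept
    jitter     max characters of boundary extension/contraction per side
    spur_rate  expected spurious spans per document (Poisson)
    """

    p_miss: float = 0.1
    p_confuse: float = 0.1
    jitter: int = 2
    spur_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_confuse"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.jitter < 0 or self.spur_rate < 0:
            raise ValueError("jitter and spur_rate must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle (roughly a tenth of the
    annotated-challenge scale: hundreds of concepts, tens of notes, a few
    thousand annotations)."""

    seed: int = 0
    n_concepts: int = 300
    branching: float = 3.0
    max_depth: int = 8
    synonyms_per_concept: tuple[int, int] = (1, 4)
    zipf_exponent: float = 1.1
    n_docs: int = 80
    anns_per_doc: tuple[int, int] = (20, 40)
    ambiguity: float = 0.1
    multi_parent_fraction: float = 0.15
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if not 0.0 <= self.ambiguity <= 1.0:
            raise ValueError("ambiguity must lie in [0, 1]")
        if self.ambiguity > 0 and self.n_concepts < 3:
            raise ValueError("ambiguity requires at least 2 non-root concepts")


@dataclass
class SyntheticBundle:
    """A complete benchmark: terminology, corpus, gold, noisy predictions,
    and a truth log sufficient to recompute expected error totals."""

    config: SimConfig
    terminology: Terminology
    docs: Corpus
    gold: AnnotationSet
    predictions: dict[str, AnnotationSet] = field(default_factory=dict)
    truth_log: dict[str, list[dict]] = field(default_factory=dict)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _lexicon_pool(rng: np.random.Generator) -> list[str]:
    pool = [f"{q} {s} {f}" for q, s, f in itertools.product(_QUALIFIERS, _SITES, _FINDINGS)]
    rng.shuffle(pool)
    return pool


def gen_terminology(config: SimConfig) -> Terminology:
    """Grow a rooted multi-hierarchy with synonym sets and shared strings."""
    rng = _rng(config.seed, 0)
    root = "1000000"
    ids = [root] + [str(1000001 + i) for i in range(config.n_concepts - 1)]
    depth = {root: 0}
    edges: list[tuple[str, str]] = []
    # attach each concept to a uniform random node above max_depth; Poisson
    # thinning is unnecessary — uniform attachment already yields mean
    # branching ≈ n/len(interior) and realistic depth spread
    for cid in ids[1:]:
        candidates = [c for c in depth if depth[c] < config.max_depth]
        parent = candidates[int(rng.integers(len(candidates)))]
        edges.append((cid, parent))
        depth[cid] = depth[parent] + 1
        if depth[cid] < config.max_depth and rng.random() < config.multi_parent_fraction:
            others = [c for c in depth if depth[c] < config.max_depth and c not in (cid, parent)]
            if others:
                second = others[int(rng.integers(len(others)))]
                edges.append((cid, second))
                depth[cid] = min(depth[cid], depth[second] + 1)

    pool = _lexicon_pool(rng)
    lo, hi = config.synonyms_per_concept
    synonyms: dict[str, list[str]] = {root: ["clinical entity (root)"]}
    cursor = 0
    for cid in ids[1:]:
        k = int(rng.integers(lo, hi + 1))
        if cursor + k > len(pool):
            raise ValueError("lexicon exhausted; reduce n_concepts or synonyms_per_concept")
        synonyms[cid] = pool[cursor : cursor + k]
        cursor += k
    # share a fraction of strings with a second concept (sibling preferred)
    term = Terminology(set(ids), synonyms, edges, root)
    non_root = ids[1:]
    if config.ambiguity > 0 and len(non_root) >= 2:
        assigned = [(cid, s) for cid in non_root for s in synonyms[cid]]
        n_shared = int(round(config.ambiguity * len(assigned)))
        picks = rng.choice(len(assigned), size=min(n_shared, len(assigned)), replace=False)
        for k in picks:
            owner, string = assigned[int(k)]
            sibs = [s for s in term.siblings(owner) if s != term.root_id]
            choicepool = sibs or [c for c in non_root if c != owner]
            target = choicepool[int(rng.integers(len(choicepool)))]
            if string not in synonyms[target]:
                synonyms[target].append(string)
        term = Terminology(set(ids), synonyms, edges, root)
    return term


def gen_corpus(term: Terminology, config: SimConfig) -> tuple[Corpus, AnnotationSet]:
    """Sectioned notes with embedded synonym mentions and exact gold offsets."""
    rng = _rng(config.seed, 1)
    mentionable = sorted(term.concept_ids - {term.root_id}) or [term.root_id]
    order = rng.permutation(len(mentionable))
    weights = np.arange(1, len(mentionable) + 1, dtype=float) ** (-config.zipf_exponent)
    weights /= weights.sum()
    ranked = [mentionable[i] for i in order]

    docs: list[Document] = []
    gold: list[SpanAnnotation] = []
    lo, hi = config.anns_per_doc
    for d in range(config.n_docs):
        doc_id = f"note{d:04d}"
        n_anns = int(rng.integers(lo, hi + 1))
        section_of = rng.integers(0, len(SECTION_HEADERS), size=n_anns)
        parts: list[str] = []
        pos = 0
        for sec_idx, header in enumerate(SECTION_HEADERS):
            parts.append(header + "\n")
            pos += len(header) + 1
            for _ in range(int((section_of == sec_idx).sum())):
                n_fill = int(rng.integers(2, 6))
                filler = " ".join(
                    _FILLER[int(rng.integers(len(_FILLER)))] for _ in range(n_fill)
                )
                parts.append(filler + " ")
                pos += len(filler) + 1
                concept = ranked[int(rng.choice(len(ranked), p=weights))]
                syns = term.synonyms[concept]
                mention = syns[int(rng.integers(len(syns)))]
                parts.append(mention)
                gold.append(SpanAnnotation(doc_id, pos, pos + len(mention), concept, "gold"))
                pos += len(mention)
                parts.append(". ")
                pos += 2
            parts.append("\n")
            pos += 1
        docs.append(Document(doc_id, "".join(parts)))
    corpus = Corpus(docs)
    gold_set = AnnotationSet("gold", gold)
    gold_set.validate_against(corpus)
    return corpus, gold_set


def perturb(
    gold: AnnotationSet,
    term: Terminology,
    docs: Corpus,
    noise: NoiseConfig,
    seed: int,
    source_id: str = "pred",
) -> tuple[AnnotationSet, list[dict]]:
    """Apply the four-channel noise process to the gold standard.

    Returns the noisy prediction set and a truth log with one event per
    gold annotation (kept / missed / confused / jitter details) plus one
    per spurious span; the log suffices to recompute expected error-type
    totals exactly.
    """
    rng = np.random.default_rng(seed)
    sibling_cache: dict[str, list[str]] = {}
    out: list[SpanAnnotation] = []
    log: list[dict] = []

    for doc_id in sorted(gold.doc_ids):
        doc_len = len(docs[doc_id]) if doc_id in docs else None
        anns = gold.for_doc(doc_id)
        prev_end = 0
        for idx, ann in enumerate(anns):
            event: dict = {
                "doc_id": doc_id, "start": ann.start, "end": ann.end,
                "concept_id": ann.concept_id,
            }
            if rng.random() < noise.p_miss:
                event["event"] = "missed"
                log.append(event)
                continue
            concept = ann.concept_id
            if rng.random() < noise.p_confuse:
                if concept not in sibling_cache:
                    sibling_cache[concept] = [
                        s for s in term.siblings(concept) if s != term.root_id
                    ] or sorted(term.concept_ids - {concept, term.root_id})
                pool = sibling_cache[concept]
                if pool:
                    concept = pool[int(rng.integers(len(pool)))]
                    event["event"] = "confused"
                    event["new_concept_id"] = concept
            start, end = ann.start, ann.end
            if noise.jitter > 0:
                ds = int(rng.integers(-noise.jitter, noise.jitter + 1))
                de = int(rng.integers(-noise.jitter, noise.jitter + 1))
                next_start = anns[idx + 1].start if idx + 1 < len(anns) else (
                    doc_len if doc_len is not None else ann.end + noise.jitter
                )
                new_start = max(ann.start + ds, prev_end, 0)
                new_end = min(ann.end + de, next_start)
                if doc_len is not None:
                    new_end = min(new_end, doc_len)
                if new_start < new_end:
                    start, end = new_start, new_end
                    if (ds, de) != (0, 0):
                        event["jitter"] = [ds, de]
                else:
                    event["jitter_skipped"] = True
            event.setdefault("event", "kept")
            event["pred_start"], event["pred_end"] = start, end
            out.append(SpanAnnotation(doc_id, start, end, concept, source_id))
            prev_end = end
            log.append(event)

    if noise.spur_rate > 0:
        concepts = sorted(term.concept_ids - {term.root_id}) or [term.root_id]
        occupied: dict[str, list[tuple[int, int]]] = {}
        for ann in itertools.chain(gold, out):
            occupied.setdefault(ann.doc_id, []).append((ann.start, ann.end))
        for doc in sorted(docs, key=lambda d: d.doc_id):
            taken = occupied.setdefault(doc.doc_id, [])
            for _ in range(int(rng.poisson(noise.spur_rate))):
                concept = concepts[int(rng.integers(len(concepts)))]
                syns = term.synonyms[concept]
                string = syns[int(rng.integers(len(syns)))]
                length = len(string)
                if length > len(doc):
                    continue
                for _attempt in range(20):
                    p = int(rng.integers(0, len(doc) - length + 1))
                    if all(not (p < e and s < p + length) for s, e in taken):
                        taken.append((p, p + length))
                        out.append(SpanAnnotation(doc.doc_id, p, p + length, concept, source_id))
                        log.append({
                            "doc_id": doc.doc_id, "start": p, "end": p + length,
                            "concept_id": concept, "event": "spurious",
                        })
                        break

    return AnnotationSet(source_id, out), log


def generate_bundle(config: SimConfig, n_systems: int = 3) -> SyntheticBundle:
    """Terminology + corpus + gold + ``n_systems`` independently noisy systems."""
    term = gen_terminology(config)
    docs, gold = gen_corpus(term, config)
    bundle = SyntheticBundle(config=config, terminology=term, docs=docs, gold=gold)
    for k in range(n_systems):
        source = f"sys{k + 1}"
        seed = int(_rng(config.seed, 2 + k).integers(0, 2**31 - 1))
        pred, log = perturb(gold, term, docs, config.noise, seed, source)
        bundle.predictions[source] = pred
        bundle.truth_log[source] = log
    return bundle


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write a bundle to the exchange formats: docs.csv, gold.csv,
    pred_<sys>.csv, terminology TSVs, truthlog.json, config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_documents(bundle.docs, outdir / "docs.csv")
    write_annotations(bundle.gold, outdir / "gold.csv")
    write_terminology(
        bundle.terminology, outdir / "terminology_synonyms.tsv", outdir / "terminology_edges.tsv"
    )
    for source, pred in bundle.predictions.items():
        write_annotations(pred, outdir / f"pred_{source}.csv")
    (outdir / "truthlog.json").write_text(
        json.dumps(bundle.truth_log, indent=1, sort_keys=True), encoding="utf-8"
    )
    cfg = asdict(bundle.config)
    cfg["root_id"] = bundle.terminology.root_id
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1), encoding="utf-8")


def estimate_noise_rates(ledger, gold: AnnotationSet, n_docs: int) -> dict[str, float]:
    """Recover the noise-channel rates from an error ledger.

    Shares of the miss and confusion channels are computed over gold-side
    record weight only (each confusion also emits a prediction-side
    False-Positive Link record, which would otherwise bias the share to
    p/(1+p)); the spurious rate is False-Positive Span records per document.
    """
    from .error_analysis import ErrorCategory, GOLD_SIDE

    weights = {cat: 0 for cat in ErrorCategory}
    counts = {cat: 0 for cat in ErrorCategory}
    for rec in ledger:
        weights[rec.category] += rec.char_weight
        counts[rec.category] += 1
    gold_weight = sum(weights[cat] for cat in GOLD_SIDE)
    return {
        "p_miss": weights[ErrorCategory.FN_SPAN] / gold_weight if gold_weight else float("nan"),
        "p_confuse": weights[ErrorCategory.FN_LINK] / gold_weight if gold_weight else float("nan"),
        "spur_per_doc": counts[ErrorCategory.FP_SPAN] / n_docs if n_docs else float("nan"),
    }
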