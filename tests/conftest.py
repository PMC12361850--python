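import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from linkeval.corpus import AnnotationSet, Corpus, Document, SpanAnnotation, Terminology
from linkeval.simulate import NoiseConfig, SimConfig, generate_bundle

#: The one-sentence note used throughout the scoring walkthrough.
SENTENCE = "CT head revealed no internal hemorrhage."
CT_HEAD_CONCEPT = "303653007"


@pytest.fixture
def ct_doc() -> Document:
    return Document("n1", SENTENCE)


@pytest.fixture
def ct_gold(ct_doc) -> AnnotationSet:
    return AnnotationSet(
        "gold", [SpanAnnotation("n1", 0, 7, CT_HEAD_CONCEPT)]
    )


@pytest.fixture
def diamond_terminology() -> Terminology:
    """root <- A, root <- B, A <- C, B <- C: a minimal multi-hierarchy."""
    ids = {"root", "A", "B", "C"}
    return Terminology(
        concept_ids=ids,
        synonyms={c: [f"{c} term"] for c in ids},
        isa_edges=[("A", "root"), ("B", "root"), ("C", "A"), ("C", "B")],
        root_id="root",
    )


@pytest.fixture(scope="session")
def clean_bundle():
    """A noise-free synthetic bundle shared across tests (read-only)."""
    config = SimConfig(
        seed=7, n_concepts=60, n_docs=12, anns_per_doc=(8, 15),
        noise=NoiseConfig(p_miss=0.0, p_confuse=0.0, jitter=0, spur_rate=0.0),
    )
    return generate_bundle(config, n_systems=2)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Noise-free bundle big enough (>10k gold characters) for rate recovery."""
    config = SimConfig(
        seed=23, n_concepts=80, n_docs=40, anns_per_doc=(18, 30),
        noise=NoiseConfig(p_miss=0.0, p_confuse=0.0, jitter=0, spur_rate=0.0),
    )
    bundle = generate_bundle(config, n_systems=1)
    assert sum(len(a) for a in bundle.gold) > 10_000
    return bundle


@pytest.fixture(scope="session")
def noisy_bundle():
    """A three-system bundle with all four noise channels active."""
    config = SimConfig(seed=11, n_concepts=80, n_docs=25, anns_per_doc=(10, 20))
    return generate_bundle(config, n_systems=3)
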