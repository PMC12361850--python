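# Methods

This note documents the models and procedures implemented in `linkeval`, the
choices that were genuinely open, and what the synthetic benchmark does and
does not establish about real clinical data.

## Scoring model

An entity-linking system is judged on whether it recovers the same
*characters* linked to the same *concept* as a gold standard.  For concept
*c*, let G_c be the set of (document, position) pairs the gold standard
assigns to *c* and P_c the set the system assigns.  The per-concept score is
the Jaccard similarity of the two character sets,

    IoU_c = |P_c ∩ G_c| / (|P_c| + |G_c| − |P_c ∩ G_c|),

and the submission score is the unweighted mean of IoU_c.  This definition
is the one consistent with the identity

    IoU_c = P·R / (P + R − P·R)

linking it to character-level precision P = |∩|/|P_c| and recall
R = |∩|/|G_c| (the identity is enforced to 1e−12 in the tests).  A widely
circulated rendering of the formula omits the −|∩| term in the denominator;
under that rendering an over-long prediction of 16 characters against a
7-character gold span would score 2/16 rather than the 7/16 this package
computes.  We implement the subtraction form because it is the one the
canonical 2/7 worked example and the precision–recall identity both
require; the discrepancy is noted here rather than silently resolved.

**Averaging domain.**  The mean runs over the union of concepts appearing
in the gold standard or the prediction.  A hallucinated concept (predicted,
never gold) enters with IoU 0; without this, inventing concepts would be
free.  The class-weighted variant weights each concept by its number of
gold annotation instances, normalized; comparing weighted to unweighted
aggregates reveals whether rare concepts are disproportionately hard.

**Degenerate cases.**  IoU of a concept absent from both sides is undefined
and such concepts are excluded (0/0 is never evaluated).  Precision is NaN
when the concept is never predicted, recall NaN when it has no gold
characters.

**Bootstrap.**  Confidence intervals resample the vector of per-concept IoU
values with replacement (default 1000 replicates, percentile 2.5/97.5), the
seed being a mandatory argument.  For the weighted mean, each resampled
concept carries its instance count and weights are renormalized per
replicate.  Calibration is checked empirically: on 500 independent
Uniform(0,1) per-concept scores the interval covers the true mean in ≈95%
of 200 repetitions.

**Inter-annotator agreement** is an instance-level Jaccard score that
deliberately ignores boundary variation: annotations from two sources match
when they are in the same document, overlap at all, and name the same
concept.  Matching is one-to-one and greedy, largest character overlap
first, ties broken by earlier start.  Whether the matching should instead
be many-to-many is not determinable from the definition alone; one-to-one
keeps the score a true Jaccard on instances.  When predictions are
boundary-exact *and* every span of a given concept has the same length, the
character-level IoU of a concept coincides with this instance-level
agreement.  With varying span lengths it does not (gold spans of lengths 10
and 2 with only the first matched give instance agreement 1/2 but character
IoU 10/12), which is why the reduction property is tested under uniform
per-concept lengths.

## Error taxonomy

Every (gold, prediction) pair in a document either overlaps (non-empty
intersection of half-open intervals) or not, and overlapping pairs either
agree on the concept or not, yielding five categories: Correct, False-
Positive/Negative Link (one linker mistake emits both, charged to the
predicted and gold concept respectively), False-Negative Span (gold
annotation overlapping no prediction) and False-Positive Span (the
converse).  The classification is a literal nested loop over gold and the
bag union of predictions: a gold annotation overlapped by k predictions
yields k pairwise records.  This double counting is intentional — it is
what the pseudocode of the procedure does — and a deduplicated variant
(one record per annotation, Correct preferred) is available behind
`dedupe=True`.

Each record is weighted by its own annotation's span length, so the
category table reports shares of affected characters.  The table is
normalized *within* each difficulty class (rows sum to 100%); normalizing
over all characters instead would make rows incomparable between classes
of very different sizes.  A concept is **hard** when its IoU falls below
the threshold (default 0.1) in *every* submission, with absence from a
report counting as 0; all other scored concepts are easy.

Rank associations use Kendall tau-b between per-concept IoU and each
difficulty feature (tau-b because feature columns such as depth are heavily
tied), and Spearman rho between two systems' per-concept IoU vectors.
Constant vectors leave both undefined: flagged with a warning, NaN.

## Concept difficulty features

For each concept: mean span length (characters, both splits);
**concept entropy**, the Shannon entropy of the bag of distinct surface
strings annotated with the concept; **annotation entropy**, the entropy of
the bag of concepts that those surface strings are linked to anywhere in
the corpus — the measure of linking ambiguity; **depth**, the shortest
is-a chain to the terminology root (root = 0, edge count, computed by BFS
on the reversed child→parent DAG); number of training examples and number
of distinct training notes.

Choices made here: entropies are in bits (base 2; any fixed base preserves
the orderings used downstream).  Surface strings are normalized (lowercase,
trim, collapse internal whitespace) before bagging, otherwise trivial
casing variants inflate both entropies.  Annotation entropy aggregates the
concept bags of the concept's *distinct* surface strings, each string
counted once; an alternative reading weights each string by its
multiplicity under the concept, exposed as
`weight_by_span_multiplicity=True`.  Example-count features use the
training split only (so a test-only concept has `n_examples = 0` but fully
defined entropies, and `n_notes ≤ n_examples` always); span length and the
entropies pool both splits, since ambiguity is a corpus property.

## Ensemble voting

The metric is defined per character, so the voting unit is the character:
each system votes one concept (or "nothing") per position, and a concept is
kept only with a strict majority of *all* systems — abstentions count in
the denominator, and ties or sub-quorum pluralities yield no annotation.
Maximal runs of an identical winning concept are reassembled into spans,
which cannot overlap by construction.  The rule is permutation-invariant
and idempotent over copies of one system.

## Synthetic benchmark generator

The generator produces the structure the analysis depends on, at desk
scale; defaults are roughly a tenth of the annotated-challenge corpus this
toolkit is designed around (hundreds of concepts, 80 notes of 20–40
annotations each ≈ 2 400 annotations, against 272 notes / 74 808
annotations / 6 624 concepts at full scale):

* **Terminology** — 300 concepts grown by uniform random attachment below
  a depth cap of 8; 15% of concepts receive a second parent (multi-
  hierarchy); 1–4 synonym strings per concept drawn from a combinatorial
  pseudo-clinical lexicon (qualifier × site × finding); 10% of strings are
  additionally assigned to a sibling concept, creating the many-to-many
  span↔concept ambiguity that drives annotation entropy.
* **Corpus** — notes with a fixed seven-section skeleton; mentions are
  synonym strings embedded between filler words with exact gold offsets;
  concept frequencies follow a Zipf law with exponent 1.1 over a random
  concept ranking, giving the heavy-tailed example distribution that makes
  rare concepts rare.
* **Noise** — per gold span, independent: dropped with `p_miss` (0.1);
  survivors re-linked with `p_confuse` (0.1) to a *sibling* concept when
  one exists (so link errors concentrate among semantically adjacent,
  high-ambiguity targets) else to a uniform other concept; boundaries
  jittered within ±2 characters, clamped so no overlap can arise (an
  unavoidable clamp-to-empty skips the jitter and is logged); spurious
  spans at Poisson rate 2 per document reuse real lexicon strings placed on
  unannotated text, so span false positives are string-plausible.  Every
  event is recorded in a truth log from which expected error-type totals
  can be recomputed exactly.

Rate recovery from the error ledger uses gold-side records only for the
miss and confusion shares: each confusion emits both a gold-side and a
prediction-side link record, so the share of FN-Link in *all* record weight
would be p/(1+p) rather than p.  The spurious rate is recovered as
FP-Span records per document.

**What the generator does not emulate**: real clinical language and its
abbreviations, annotator disagreement (the gold standard is single-source
and internally consistent), correlated errors between systems, section-
dependent concept distributions, and deidentification artifacts.  Two
consequences matter when reading results.  First, majority voting over
independently corrupted systems improves scores far more on synthetic data
than it can on real systems, whose errors are strongly rank-correlated.
Second, the synthetic hard/easy error profile differs from real data: here
hard concepts are dominated by link confusions and spurious strings, while
real corpora show recall-dominated failure concentrated in concepts with
very few training examples.  Passing tests therefore demonstrate the
correctness of the measurement machinery, not any claim about how actual
entity linkers perform.

## Problem sizes and numerical choices

Unit and property tests run on corpora of ≤ 5 documents × ≤ 200 characters
(where brute-force character-set oracles are exact and cheap) and on
bundles of 12–80 notes; noise-rate recovery uses a 40-note bundle with
> 10 000 gold characters, where binomial sampling error is within the
±0.03 band checked.  All randomness flows through explicitly seeded
`numpy` generators; identical (config, seed) reproduces bundles
byte-for-byte through the writers.  Character offsets are 0-based,
half-open, over decoded characters (not bytes); empty spans are rejected at
construction, and annotation sets from one source must be overlap-free —
mirroring annotation guidelines that preclude overlapping spans.
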