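# linkeval

Evaluation and error analysis for **clinical entity linking** — the task of
finding the text spans in a clinical note that denote clinical entities and
mapping each span to a concept in a terminology such as SNOMED CT.

The package is aimed at people who run or study entity-linking evaluations:
it implements the character-level scoring used to rank systems, the error
taxonomy used to explain *why* concepts score poorly, the concept-level
difficulty features (entropy, ambiguity, frequency, hierarchy depth), a
character-level majority-vote ensemble, and a synthetic benchmark generator
so that the entire stack is testable without access to any restricted
clinical corpus.

## The metric

For a concept *c*, with G_c the set of (document, position) character pairs
the gold standard links to *c* and P_c the set a system links to *c*:

    IoU_c = |P_c ∩ G_c| / (|P_c| + |G_c| − |P_c ∩ G_c|)

The submission score is the mean of IoU_c over all concepts appearing in
either the gold standard or the prediction, so hallucinated concepts are
penalized.  IoU_c relates to character-level precision and recall through
IoU = P·R/(P + R − P·R).  A class-weighted variant weights each concept by
its number of gold instances.  Canonical example: for the sentence
`CT head revealed no internal hemorrhage.` with gold span `CT head` linked
to concept 303653007, a prediction covering only `CT` with the same concept
scores 2/7 ≈ 0.286; the same span linked to a different concept scores 0.

On top of the metric the package provides:

* **Error taxonomy** — every gold/predicted annotation is classified as
  Correct, False-Positive/Negative Link (overlapping spans, wrong concept)
  or False-Positive/Negative Span (no overlap at all), with character
  weights, cross-tabulated over a hard/easy concept partition
  (hard = IoU < 0.1 in every submission).
* **Difficulty features** — mean span length, concept entropy (diversity
  of a concept's surface strings), annotation entropy (ambiguity of those
  strings as linking targets), is-a depth, training-example and note
  counts, plus Kendall-tau associations with per-concept IoU and Spearman
  correlations between systems.
* **Ensemble** — strict per-character majority voting across systems.
* **Synthetic benchmarks** — multi-hierarchy terminologies with shared
  synonyms, sectioned notes with Zipf-distributed concept frequencies, and
  a four-channel noise process (miss / sibling-confusion / boundary jitter
  / spurious spans) with a complete truth log.

## Worked example

```python
from linkeval import (SimConfig, generate_bundle, score_submission,
                      bootstrap_ci, majority_vote, partition_hard_easy,
                      classify_errors, error_table)

bundle = generate_bundle(SimConfig(seed=7), n_systems=3)
reports = {}
for name, pred in bundle.predictions.items():
    r = score_submission(bundle.gold, pred)
    lo, hi = bootstrap_ci(r, n_boot=1000, seed=0)
    reports[name] = r
    print(f"{name}: mean IoU {r.mean_iou:.3f} [{lo:.3f}, {hi:.3f}]  "
          f"weighted {r.weighted_iou:.3f}")

voted = majority_vote(list(bundle.predictions.values()))
rv = score_submission(bundle.gold, voted)
print(f"vote: mean IoU {rv.mean_iou:.3f}  weighted {rv.weighted_iou:.3f}")
```

prints

```
sys1: mean IoU 0.522 [0.487, 0.560]  weighted 0.701
sys2: mean IoU 0.509 [0.475, 0.544]  weighted 0.706
sys3: mean IoU 0.519 [0.484, 0.554]  weighted 0.692
vote: mean IoU 0.830  weighted 0.836
```

Each line is one noisy synthetic system scored against the gold standard:
the mean per-concept IoU with its bootstrap 95% interval, then the
class-weighted mean.  The weighted mean is higher than the unweighted one
because the generator's Zipf frequency law makes rare concepts — which the
noise hurts most in per-concept terms — carry little instance weight, the
same signature seen in real evaluations.  The voted ensemble improves
sharply here because the three systems' errors are independent by
construction; real systems' errors are strongly correlated, so real
ensembles gain far less (see `docs/methods.md`).

The error breakdown for the same bundle:

```python
part = partition_hard_easy(reports.values(), threshold=0.1)
ledger = classify_errors(bundle.gold, list(bundle.predictions.values()))
print(error_table(ledger, part).round(1))
```

gives the character-weighted percentage of each error category within the
hard and easy concept classes (rows sum to 100).

A command-line interface mirrors the library:
`linkeval score|errors|features|vote|simulate|run` — for example

```bash
linkeval simulate --seed 7 --systems 3 --out bundle/
linkeval score --gold bundle/gold.csv --pred bundle/pred_sys1.csv \
    --boot 1000 --seed 0 --out report.json
```

Exchange formats are plain text: annotation CSVs with columns
`note_id,start,end,concept_id` (0-based, half-open character offsets),
documents as a `note_id,text` CSV or a directory of text files, and
terminologies as two TSVs (concept synonyms; child→parent is-a edges).

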