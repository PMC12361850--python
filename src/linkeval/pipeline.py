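"""One-shot evaluation pipeline: score → errors → features → vote → report.

Given a corpus, gold annotations (train/test), one or more prediction sets
and a terminology, :func:`run_pipeline` writes per-system score reports,
the hard/easy difficulty partition, the character-weighted error-category
table, the concept feature table, feature/IoU rank associations, pairwise
inter-system correlations, and the majority-vote ensemble scores, plus a
manifest with seeds and input digests for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .concept_features import feature_table
from .corpus import (
    AnnotationSet,
    Corpus,
    read_annotations,
    read_documents,
    read_terminology,
    write_annotations,
)
from .ensemble import VoteConfig, majority_vote
from .error_analysis import (
    classify_errors,
    error_table,
    feature_associations,
    partition_hard_easy,
    system_correlation,
)
from .scoring import ScoreReport, bootstrap_ci, score_submission

logger = logging.getLogger("linkeval.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run (all paths are exchange formats)."""

    docs: str
    gold_test: str
    predictions: Mapping[str, str]  # source_id -> path
    gold_train: str | None = None
    terminology_synonyms: str | None = None
    terminology_edges: str | None = None
    terminology_root: str | None = None
    threshold: float = 0.1
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "linkeval_out"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _report_json(report: ScoreReport) -> dict:
    return {
        "source_id": report.source_id,
        "mean_iou": report.mean_iou,
        "weighted_iou": report.weighted_iou,
        "n_concepts": report.n_concepts,
        "ci_low": report.ci_low,
        "ci_high": report.ci_high,
        "n_boot": report.n_boot,
        "seed": report.seed,
        "per_concept": {
            cid: {
                "iou": s.iou,
                "precision": s.precision,
                "recall": s.recall,
                "n_gt_chars": s.n_gt_chars,
                "n_pred_chars": s.n_pred_chars,
                "n_intersect_chars": s.n_intersect_chars,
                "n_gt_instances": s.n_gt_instances,
            }
            for cid, s in report.per_concept.items()
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full evaluation and write all artifacts to ``config.outdir``.

    Returns a summary dict (also written as ``summary.json``).  Any stage
    failure aborts with the stage name in the log record.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "inputs": {}, "stages": []}

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    stage("load")
    docs = read_documents(config.docs)
    gold = read_annotations(config.gold_test, "gold")
    gold.validate_against(docs)
    manifest["inputs"][config.docs] = _sha256(config.docs)
    manifest["inputs"][config.gold_test] = _sha256(config.gold_test)
    preds: dict[str, AnnotationSet] = {}
    for source, path in config.predictions.items():
        preds[source] = read_annotations(path, source)
        manifest["inputs"][str(path)] = _sha256(path)
    train = None
    if config.gold_train:
        train = read_annotations(config.gold_train, "gold")
        manifest["inputs"][config.gold_train] = _sha256(config.gold_train)
    term = None
    if config.terminology_synonyms and config.terminology_edges and config.terminology_root:
        term = read_terminology(
            config.terminology_synonyms, config.terminology_edges, config.terminology_root
        )
        manifest["inputs"][config.terminology_synonyms] = _sha256(config.terminology_synonyms)
        manifest["inputs"][config.terminology_edges] = _sha256(config.terminology_edges)

    stage("score")
    reports: dict[str, ScoreReport] = {}
    for source, pred in preds.items():
        report = score_submission(gold, pred)
        bootstrap_ci(report, n_boot=config.n_boot, seed=config.seed)
        reports[source] = report
        (outdir / f"scores_{source}.json").write_text(
            json.dumps(_report_json(report), indent=1), encoding="utf-8"
        )

    stage("partition")
    partition = partition_hard_easy(reports.values(), config.threshold)
    (outdir / "partition.json").write_text(
        json.dumps(
            {
                "threshold": partition.threshold,
                "hard": sorted(partition.hard),
                "easy": sorted(partition.easy),
            },
            indent=1,
        ),
        encoding="utf-8",
    )

    stage("errors")
    ledger = classify_errors(gold, list(preds.values()))
    table = error_table(ledger, partition)
    table.to_csv(outdir / "error_table.csv", index_label="class")
    ledger.to_frame().to_csv(outdir / "errors.csv", index=False)

    summary: dict = {
        "mean_iou": {s: r.mean_iou for s, r in reports.items()},
        "weighted_iou": {s: r.weighted_iou for s, r in reports.items()},
        "ci": {s: [r.ci_low, r.ci_high] for s, r in reports.items()},
        "n_hard": len(partition.hard),
        "n_easy": len(partition.easy),
        "error_table": {cls: table.loc[cls].to_dict() for cls in table.index},
    }

    if train is not None:
        stage("features")
        features = feature_table(train, gold, docs, term)
        features.to_csv(outdir / "features.csv")
        assoc = {
            source: feature_associations(report, features).to_dict()
            for source, report in reports.items()
        }
        (outdir / "associations.json").write_text(json.dumps(assoc, indent=1), encoding="utf-8")
        summary["associations"] = assoc

    sources = sorted(reports)
    if len(sources) >= 2:
        stage("correlation")
        summary["spearman"] = {
            f"{a}|{b}": system_correlation(reports[a], reports[b])
            for i, a in enumerate(sources)
            for b in sources[i + 1 :]
        }

        stage("vote")
        voted = majority_vote([preds[s] for s in sources], VoteConfig())
        write_annotations(voted, outdir / "voted.csv")
        voted_report = score_submission(gold, voted)
        bootstrap_ci(voted_report, n_boot=config.n_boot, seed=config.seed)
        (outdir / "scores_vote.json").write_text(
            json.dumps(_report_json(voted_report), indent=1), encoding="utf-8"
        )
        summary["mean_iou"]["vote"] = voted_report.mean_iou
        summary["weighted_iou"]["vote"] = voted_report.weighted_iou

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1), encoding="utf-8")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return summary
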