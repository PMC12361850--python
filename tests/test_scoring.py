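"""Character-level IoU scoring, aggregates, bootstrap, and agreement."""

import math

import numpy as np
import pytest

from linkeval.corpus import AnnotationSet, SpanAnnotation
from linkeval.scoring import (
    bootstrap_ci,
    char_assignment,
    concept_iou,
    concept_precision_recall,
    iaa_jaccard,
    score_submission,
)

from oracles import brute_iou, brute_precision_recall, random_case

C = "303653007"


def _sets(gold_spans, pred_spans):
    gt = AnnotationSet("gold", [SpanAnnotation(*s) for s in gold_spans])
    pred = AnnotationSet("pred", [SpanAnnotation(*s) for s in pred_spans])
    return gt, pred


class TestCharAssignment:
    def test_total_chars_is_sum_of_span_lengths(self):
        aset = AnnotationSet("s", [SpanAnnotation("n1", 0, 2, "a"), SpanAnnotation("n1", 5, 9, "b")])
        ca = char_assignment(aset)
        assert ca.total_chars == 6
        assert ca.n_chars("a") == 2 and ca.n_chars("b") == 4

    def test_positions_carry_the_covering_concept(self):
        ca = char_assignment(AnnotationSet("s", [SpanAnnotation("n1", 0, 7, C)]))
        assert ca.concept_at("n1", 0) == C and ca.concept_at("n1", 6) == C
        assert ca.concept_at("n1", 7) is None

    def test_empty_set_gives_empty_assignment(self):
        assert char_assignment(AnnotationSet("s")).total_chars == 0


class TestConceptIoU:
    def test_short_prediction_penalized_for_missing_characters(self):
        # gold "CT head" (7 chars), prediction "CT" (2 chars): 2 / 7
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 2, C)])
        iou = concept_iou(char_assignment(gt), char_assignment(pred), C)
        assert iou == pytest.approx(2 / 7)
        assert round(iou, 3) == 0.286

    def test_wrong_concept_scores_zero_for_the_gold_concept(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 7, "999")])
        assert concept_iou(char_assignment(gt), char_assignment(pred), C) == 0.0

    def test_overlong_prediction_penalized_through_the_union(self):
        # "CT head revealed" (16 chars) over gold "CT head": 7 / 16
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 16, C)])
        assert concept_iou(char_assignment(gt), char_assignment(pred), C) == pytest.approx(7 / 16)

    def test_identical_sets_score_one(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 7, C)])
        assert concept_iou(char_assignment(gt), char_assignment(pred), C) == 1.0

    def test_unknown_concept_is_a_domain_error(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 7, C)])
        with pytest.raises(ValueError):
            concept_iou(char_assignment(gt), char_assignment(pred), "absent")

    def test_matches_character_set_oracle_on_random_corpora(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            _, gt, pred = random_case(rng)
            ga, pa = char_assignment(gt), char_assignment(pred)
            for concept in gt.concept_ids | pred.concept_ids:
                assert concept_iou(ga, pa, concept) == pytest.approx(
                    brute_iou(gt, pred, concept), abs=0
                )

    def test_monotone_in_correct_and_spurious_characters(self):
        gt, _ = _sets([("n1", 0, 7, C)], [])
        ga = char_assignment(gt)

        def iou_of_pred(end):
            return concept_iou(ga, char_assignment(_sets([], [("n1", 0, end, C)])[1]), C)

        # growing into the gold span adds correct characters: non-decreasing
        grow = [iou_of_pred(e) for e in range(1, 8)]
        assert all(a <= b for a, b in zip(grow, grow[1:])) and grow[-1] == 1.0
        # growing past it adds spurious characters: non-increasing
        overshoot = [iou_of_pred(e) for e in range(7, 12)]
        assert all(a >= b for a, b in zip(overshoot, overshoot[1:]))


class TestPrecisionRecallIdentity:
    def test_short_prediction(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 2, C)])
        p, r = concept_precision_recall(char_assignment(gt), char_assignment(pred), C)
        assert (p, r) == (1.0, pytest.approx(2 / 7))

    def test_overlong_prediction(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 16, C)])
        p, r = concept_precision_recall(char_assignment(gt), char_assignment(pred), C)
        assert (p, r) == (pytest.approx(7 / 16), 1.0)

    def test_identity_iou_equals_pr_over_p_plus_r_minus_pr(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(100):
            _, gt, pred = random_case(rng, min_spans_per_doc=2)
            ga, pa = char_assignment(gt), char_assignment(pred)
            for concept in gt.concept_ids | pred.concept_ids:
                p, r = concept_precision_recall(ga, pa, concept)
                if math.isnan(p) or math.isnan(r) or p == 0 or r == 0:
                    continue
                iou = concept_iou(ga, pa, concept)
                assert abs(iou - p * r / (p + r - p * r)) < 1e-12
                checked += 1
        assert checked > 100

    def test_pr_matches_character_set_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            _, gt, pred = random_case(rng)
            ga, pa = char_assignment(gt), char_assignment(pred)
            for concept in gt.concept_ids | pred.concept_ids:
                got = concept_precision_recall(ga, pa, concept)
                want = brute_precision_recall(gt, pred, concept)
                for g, w in zip(got, want):
                    assert (math.isnan(g) and math.isnan(w)) or g == pytest.approx(w, abs=0)


class TestScoreSubmission:
    def test_perfect_submission_scores_one_everywhere(self):
        spans = [("n1", 0, 7, C), ("n1", 10, 14, "222")]
        gt, pred = _sets(spans, spans)
        report = score_submission(gt, pred)
        assert report.mean_iou == 1.0 and report.weighted_iou == 1.0

    def test_empty_prediction_scores_zero(self):
        gt, pred = _sets([("n1", 0, 7, C)], [])
        report = score_submission(gt, pred)
        assert report.mean_iou == 0.0

    def test_hallucinated_concept_enters_the_averaging_domain(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 7, C), ("n1", 10, 14, "999")])
        report = score_submission(gt, pred)
        assert report.n_concepts == 2
        assert report.mean_iou == pytest.approx(0.5)

    def test_weighting_by_gold_instance_counts(self):
        # concept A: 9 instances all found (IoU 1); concept B: 1 instance missed (IoU 0)
        gold = [("n1", 10 * i, 10 * i + 5, "A") for i in range(9)] + [("n1", 95, 99, "B")]
        pred = [("n1", 10 * i, 10 * i + 5, "A") for i in range(9)]
        gt, pr = _sets(gold, pred)
        report = score_submission(gt, pr)
        assert report.mean_iou == pytest.approx(0.5)
        assert report.weighted_iou == pytest.approx(0.9)

    def test_disjoint_corpora_warn_and_score_zero(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n2", 0, 7, C)])
        with pytest.warns(UserWarning, match="share no"):
            report = score_submission(gt, pred)
        assert report.mean_iou == 0.0


class TestBootstrap:
    def test_zero_variance_gives_degenerate_interval(self):
        gold = [("n1", 10 * i, 10 * i + 5, f"c{i}") for i in range(4)]
        gt, pred = _sets(gold, gold)
        report = score_submission(gt, pred)
        low, high = bootstrap_ci(report, n_boot=200, seed=1)
        assert low == high == 1.0

    def test_reproducible_for_fixed_seed(self):
        # gold concepts found with varying partial overlap -> spread of IoUs
        gold = [("n1", 10 * i, 10 * i + 8, f"c{i}") for i in range(8)]
        pred = [("n1", 10 * i, 10 * i + 8 - i, f"c{i}") for i in range(7)]
        gt, pr = _sets(gold, pred)
        r1 = score_submission(gt, pr)
        r2 = score_submission(gt, pr)
        assert bootstrap_ci(r1, n_boot=500, seed=9) == bootstrap_ci(r2, n_boot=500, seed=9)
        assert bootstrap_ci(r1, n_boot=500, seed=10) != bootstrap_ci(r1, n_boot=500, seed=9)

    def test_interval_brackets_the_point_estimate(self):
        gold = [("n1", 12 * i, 12 * i + 9, f"c{i}") for i in range(9)]
        pred = [("n1", 12 * i, 12 * i + 9 - i % 5, f"c{i}") for i in range(6)]
        gt, pred = _sets(gold, pred)
        report = score_submission(gt, pred)
        low, high = bootstrap_ci(report, n_boot=1000, seed=2)
        assert 0.0 <= low <= report.mean_iou <= high <= 1.0
        wlow, whigh = bootstrap_ci(report, n_boot=1000, seed=2, weighted=True)
        assert 0.0 <= wlow <= report.weighted_iou <= whigh <= 1.0

    def test_single_concept_unweighted_is_flagged_degenerate(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 7, C)])
        report = score_submission(gt, pred)
        with pytest.warns(UserWarning, match="degenerate"):
            low, high = bootstrap_ci(report, n_boot=10, seed=0)
        assert low == high


class TestIaaJaccard:
    def test_identical_annotators_agree_perfectly(self):
        gt, _ = _sets([("n1", 0, 7, C), ("n2", 3, 9, "222")], [])
        b = AnnotationSet("b", [SpanAnnotation(a.doc_id, a.start, a.end, a.concept_id) for a in gt])
        assert iaa_jaccard(gt, b) == 1.0

    def test_no_overlapping_pairs_scores_zero(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 20, 25, C)])
        assert iaa_jaccard(gt, pred) == 0.0

    def test_boundary_variation_ignored(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 2, C)])
        assert iaa_jaccard(gt, pred) == 1.0

    def test_concept_disagreement_counts_as_mismatch(self):
        gt, pred = _sets([("n1", 0, 7, C)], [("n1", 0, 7, "999")])
        assert iaa_jaccard(gt, pred) == 0.0

    def test_one_to_one_matching_is_greedy_on_overlap(self):
        # one annotation in a, two same-concept candidates in b: only one match
        a = AnnotationSet("a", [SpanAnnotation("n1", 0, 10, C)])
        b = AnnotationSet("b", [SpanAnnotation("n1", 0, 4, C), SpanAnnotation("n1", 5, 10, C)])
        assert iaa_jaccard(a, b) == pytest.approx(1 / 2)


class TestBoundaryExactReduction:
    def test_mean_iou_reduces_to_per_concept_instance_jaccard(self):
        """With boundary-exact predictions and per-concept uniform span
        lengths, IoU_c equals the instance-level Jaccard agreement for c."""
        rng = np.random.default_rng(12)
        length = {f"c{k}": 4 + k for k in range(4)}
        for _ in range(25):
            gold, pred = [], []
            pos = 0
            for _ in range(int(rng.integers(4, 12))):
                concept = f"c{int(rng.integers(4))}"
                span = ("n1", pos, pos + length[concept], concept)
                gold.append(span)
                keep = rng.random()
                if keep < 0.5:
                    pred.append(span)  # exact match
                elif keep < 0.7:
                    pred.append((span[0], span[1], span[2], "c_other"))  # relink, exact bounds
                pos += length[concept] + int(rng.integers(1, 5))
            if rng.random() < 0.5 and gold:  # boundary-exact spurious duplicate elsewhere
                concept = f"c{int(rng.integers(4))}"
                pred.append(("n1", pos, pos + length[concept], concept))
            gt, pr = _sets(gold, pred)
            ga, pa = char_assignment(gt), char_assignment(pr)
            for concept in gt.concept_ids | pr.concept_ids:
                a_c = AnnotationSet("gold", gt.for_concept(concept))
                b_c = AnnotationSet("pred", [
                    SpanAnnotation(x.doc_id, x.start, x.end, x.concept_id)
                    for x in pr.for_concept(concept)
                ])
                if len(a_c) == 0 and len(b_c) == 0:
                    continue
                assert concept_iou(ga, pa, concept) == pytest.approx(iaa_jaccard(a_c, b_c))
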