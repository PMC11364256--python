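"""Open-set metrics against enumeration oracles and hand-worked examples."""

import numpy as np
import pytest

from conftest import make_records
from echoviews.evalmetrics import (EvalRecord, build_report,
                                   closed_set_accuracy, full_set_accuracy,
                                   open_confusion_matrix, oscr_auc,
                                   oscr_curve, ovo_roc_auc,
                                   per_subcategory_roc, spearman, tpr_fpr,
                                   unknown_roc_auc)
from oracles import (oracle_closed_accuracy, oracle_full_set_accuracy,
                     oracle_oscr, oracle_ovo_auc, oracle_tpr_fpr,
                     oracle_unknown_auc, random_open_set_instance)


class TestHandWorkedExamples:
    def test_closed_set_accuracy_ignores_unknowns(self):
        recs = make_records([0, 1, 1], [0, 1, 0], [1.0, 1.0, 1.0])
        assert closed_set_accuracy(recs) == pytest.approx(2 / 3)
        extra = make_records(["poor_quality"] * 5, [0] * 5, [0.0] * 5)
        assert closed_set_accuracy(recs + extra) == pytest.approx(2 / 3)

    def test_five_record_set_at_half(self, five_record_set):
        assert full_set_accuracy(five_record_set, 0.5) == pytest.approx(2 / 5)
        tpr, fpr, bal = tpr_fpr(five_record_set, 0.5)
        assert tpr == pytest.approx(2 / 3)
        assert fpr == pytest.approx(1 / 2)
        assert bal == pytest.approx(7 / 12)
        assert oracle_oscr([r.true_label for r in five_record_set],
                           [r.predicted_class for r in five_record_set],
                           [r.score for r in five_record_set], 0.5) \
            == pytest.approx(1 / 3)

    def test_full_set_accuracy_limits(self, five_record_set):
        assert full_set_accuracy(five_record_set, -np.inf) == pytest.approx(2 / 5)
        assert full_set_accuracy(five_record_set, np.inf) == pytest.approx(2 / 5)
        # generic identities: A(-inf) = closed-correct/total, A(inf) = unknown share
        recs = make_records([0, 0, 1, "novel_category"], [0, 1, 1, 0],
                            [1, 2, 3, 4.0])
        assert full_set_accuracy(recs, -np.inf) == pytest.approx(2 / 4)
        assert full_set_accuracy(recs, np.inf) == pytest.approx(1 / 4)

    def test_tpr_fpr_limits(self, five_record_set):
        assert tpr_fpr(five_record_set, -np.inf) == pytest.approx((1, 1, 0.5))
        assert tpr_fpr(five_record_set, np.inf) == pytest.approx((0, 0, 0.5))

    def test_errors_on_missing_sides(self):
        knowns = make_records([0, 1], [0, 1], [1.0, 2.0])
        with pytest.raises(ValueError):
            tpr_fpr(knowns, 0.0)
        with pytest.raises(ValueError):
            closed_set_accuracy(make_records(["poor_quality"], [0], [1.0]))


class TestCurves:
    def test_oscr_below_tpr_everywhere(self, five_record_set):
        from echoviews.openset import candidate_thresholds
        scores = [r.score for r in five_record_set]
        for d in candidate_thresholds(np.array(scores)):
            tpr, _, _ = tpr_fpr(five_record_set, d)
            oscr = oracle_oscr([r.true_label for r in five_record_set],
                               [r.predicted_class for r in five_record_set],
                               scores, d)
            assert oscr <= tpr + 1e-12

    def test_perfect_scorer_has_unit_aucs(self):
        recs = make_records([0, 1, "novel_category", "poor_quality"],
                            [0, 1, 0, 0], [5.0, 4.0, 1.0, 0.5])
        assert oscr_auc(oscr_curve(recs)) == pytest.approx(1.0)
        assert unknown_roc_auc(recs) == pytest.approx(1.0)

    def test_oscr_curve_spans_fpr_zero_to_one(self, five_record_set):
        pts = oscr_curve(five_record_set)
        assert pts[0, 0] == 0.0 and pts[-1, 0] == 1.0
        assert (np.diff(pts[:, 0]) >= 0).all()


class TestOracleEquivalence:
    def test_metrics_match_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            labels, preds, scores, class_scores, C = \
                random_open_set_instance(rng)
            recs = make_records(labels, preds, scores)
            delta = float(rng.choice(scores))
            assert closed_set_accuracy(recs) == pytest.approx(
                oracle_closed_accuracy(labels, preds))
            assert full_set_accuracy(recs, delta) == pytest.approx(
                oracle_full_set_accuracy(labels, preds, scores, delta))
            assert tpr_fpr(recs, delta) == pytest.approx(
                oracle_tpr_fpr(labels, scores, delta))
            assert unknown_roc_auc(recs) == pytest.approx(
                oracle_unknown_auc(labels, scores))
            assert ovo_roc_auc(recs, class_scores) == pytest.approx(
                oracle_ovo_auc(labels, class_scores))

    def test_ovo_three_class_toy_matches_pair_counting(self):
        labels = [0, 0, 1, 1, 2, 2, 2]
        class_scores = np.array([[3, 0, 1], [2, 1, 0], [0, 2, 1], [1, 3, 0],
                                 [0, 1, 2], [1, 0, 3], [0, 0, 2]], float)
        recs = make_records(labels, [0] * 7, [1.0] * 7)
        assert ovo_roc_auc(recs, class_scores) == pytest.approx(
            oracle_ovo_auc(labels, class_scores))

    def test_unknown_auc_tie_convention(self):
        recs = make_records([0, "novel_category"], [0, 0], [1.0, 1.0])
        assert unknown_roc_auc(recs) == pytest.approx(0.5)


class TestSpearman:
    def test_monotone_reversed_and_tied_ranks(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert spearman([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestConfusionMatrix:
    def test_reject_all_populates_unknown_column_only(self, five_record_set):
        cm = open_confusion_matrix(five_record_set, np.inf, 2)
        assert cm.sum() == 5
        assert cm[:, :-1].sum() == 0

    def test_five_record_set_sums(self, five_record_set):
        cm = open_confusion_matrix(five_record_set, 0.5, 2)
        assert cm.sum() == 5
        assert cm.sum(axis=1)[-1] == 2  # unknown reference row
        assert cm.sum(axis=1)[:2].sum() == 3

    def test_known_trace_counts_accepted_correct(self, five_record_set):
        cm = open_confusion_matrix(five_record_set, 0.5, 2)
        assert np.trace(cm[:2, :2]) == 1


class TestPerSubcategory:
    def test_matches_manual_filtering(self, five_record_set):
        out = per_subcategory_roc(five_record_set)
        assert set(out) == {"novel_category", "poor_quality"}
        manual = [r for r in five_record_set
                  if r.is_known or r.true_label == "novel_category"]
        assert out["novel_category"]["auc"] == pytest.approx(
            unknown_roc_auc(manual))

    def test_missing_subcategory_warns(self, five_record_set):
        with pytest.warns(UserWarning, match="multiple_views"):
            per_subcategory_roc(five_record_set)

    def test_separable_toy_all_unit(self):
        labels = [0, 1, "novel_category", "poor_quality", "multiple_views"]
        recs = make_records(labels, [0, 1, 0, 0, 0], [5, 6, 1, 2, 0.5])
        out = per_subcategory_roc(recs)
        assert all(v["auc"] == pytest.approx(1.0) for v in out.values())


def test_summarize_runs_gives_mean_and_sd():
    from echoviews.evalmetrics import summarize_runs
    runs = [{"closed": 0.9, "oscr_auc": 0.8, "note": "a"},
            {"closed": 0.8, "oscr_auc": 0.6, "note": "b"}]
    out = summarize_runs(runs)
    assert out["closed"] == pytest.approx((0.85, 0.05))
    assert out["oscr_auc"] == pytest.approx((0.7, 0.1))
    assert "note" not in out


def test_build_report_is_internally_consistent(five_record_set):
    rep = build_report(five_record_set, 0.5, 2)
    assert rep.full_set_accuracy == pytest.approx(2 / 5)
    assert rep.balanced_accuracy == pytest.approx((rep.tpr + 1 - rep.fpr) / 2)
    assert rep.confusion_matrix.sum() == 5
    d = rep.to_dict()
    assert set(d["per_subcategory_auc"]) == {"novel_category", "poor_quality"}
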