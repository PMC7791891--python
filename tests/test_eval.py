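"""Confidence filter, one-to-one matching, and detection metrics."""

import math

import numpy as np
import pytest

from immunoseg.evaluate import (
    class_metrics,
    cross_evaluate,
    filter_confidence,
    match_instances,
    overall_metrics,
)
from immunoseg.model import CohortDataset, ImageFrame

from conftest import brute_force_best_matching, random_matching_scenario, square_instance


def _frame(instances, fid="f", size=64):
    return ImageFrame(frame_id=fid, width_px=size, height_px=size,
                      pixel_size_um=1.0, fixation="FFPE", panel="panel2",
                      instances=instances)


class TestFilterConfidence:
    def test_threshold_is_strict(self):
        frame = _frame([
            square_instance(1, confidence=0.29, source="predicted", x0=2, y0=2),
            square_instance(2, confidence=0.30, source="predicted", x0=20, y0=2),
            square_instance(3, confidence=0.31, source="predicted", x0=40, y0=2),
        ])
        kept = filter_confidence(frame, 0.3)
        assert [s.id for s in kept.instances] == [3]

    def test_empty_frame_passes_through(self):
        assert filter_confidence(_frame([]), 0.3).instances == []

    def test_manual_frame_unchanged(self):
        frame = _frame([square_instance(1, x0=2, y0=2), square_instance(2, x0=20, y0=2)])
        assert len(filter_confidence(frame, 0.3).instances) == 2

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_threshold_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            filter_confidence(_frame([]), bad)


class TestMatchInstances:
    def test_perfect_overlap_single_pair(self):
        truth = _frame([square_instance(1, x0=5, y0=5)])
        pred = _frame([square_instance(1, x0=5, y0=5, confidence=0.9, source="predicted")])
        ms = match_instances(truth, pred)
        assert ms.pairs == [(1, 1, 1.0)]
        assert ms.unmatched_truth == [] and ms.unmatched_pred == []

    def test_overlap_below_threshold_counts_fn_and_fp(self):
        # 10x10 squares offset by 6.6 px: intersection 30, union 170, IOU ~0.176
        truth = _frame([square_instance(1, x0=0, y0=0)])
        pred = _frame([square_instance(1, x0=6.6, y0=0, confidence=0.9, source="predicted")])
        ms = match_instances(truth, pred, theta=0.25)
        assert ms.pairs == []
        assert ms.unmatched_truth == [1] and ms.unmatched_pred == [1]

    def test_iou_exactly_at_threshold_is_matched(self):
        # offset 6 px: intersection 40, union 160, IOU = 0.25 ("at least")
        truth = _frame([square_instance(1, x0=0, y0=0)])
        pred = _frame([square_instance(1, x0=6, y0=0, confidence=0.9, source="predicted")])
        ms = match_instances(truth, pred, theta=0.25)
        assert len(ms.pairs) == 1
        assert ms.pairs[0][2] == pytest.approx(0.25)

    def test_cross_class_overlap_never_pairs(self):
        truth = _frame([square_instance(1, cell_class="pDC", x0=5, y0=5)])
        pred = _frame([square_instance(1, cell_class="CD4T", x0=5, y0=6,
                                       confidence=0.9, source="predicted")])
        ms = match_instances(truth, pred)
        assert ms.pairs == []
        assert ms.unmatched_truth == [1] and ms.unmatched_pred == [1]

    def test_duplicate_detections_keep_best_iou_other_is_fp(self):
        truth = _frame([square_instance(1, x0=10, y0=10)])
        pred = _frame([
            square_instance(1, x0=12, y0=10, confidence=0.9, source="predicted"),  # IOU 2/3
            square_instance(2, x0=14, y0=10, confidence=0.9, source="predicted"),  # IOU 0.43
        ])
        ms = match_instances(truth, pred)
        assert len(ms.pairs) == 1
        assert ms.pairs[0][:2] == (1, 1)
        assert ms.unmatched_pred == [2]

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            match_instances(_frame([], size=64), _frame([], size=32))

    def test_matches_brute_force_oracle_on_random_frames(self):
        """Pair count and total IOU equal exhaustive assignment enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            truth, pred = random_matching_scenario(rng)
            ms = match_instances(truth, pred, theta=0.25)
            count, total = brute_force_best_matching(truth, pred, theta=0.25)
            assert len(ms.pairs) == count
            assert sum(p[2] for p in ms.pairs) == pytest.approx(total)

    def test_raising_theta_never_increases_matches(self):
        rng = np.random.default_rng(7)
        truth, pred = random_matching_scenario(rng, max_cells=6)
        counts = [len(match_instances(truth, pred, theta=t).pairs)
                  for t in (0.1, 0.25, 0.5, 0.75)]
        assert counts == sorted(counts, reverse=True)


class TestMetrics:
    def test_conservation_of_counts_per_class(self):
        rng = np.random.default_rng(99)
        matchsets = []
        frames = []
        for k in range(10):
            truth, pred = random_matching_scenario(rng)
            truth.frame_id = pred.frame_id = f"f{k}"
            frames.append((truth, pred))
            matchsets.append(match_instances(truth, pred))
        for m in class_metrics(matchsets):
            assert m.tp + m.fn == m.n_truth
            assert m.tp + m.fp == m.n_pred
            assert m.tp <= min(m.n_truth, m.n_pred)

    def test_ppv_specificity_from_counts(self):
        truth = _frame([square_instance(i, x0=6 * i, y0=2, side=4) for i in range(1, 10)])
        preds = [square_instance(i, x0=6 * i, y0=2, side=4, confidence=0.9, source="predicted")
                 for i in range(1, 10)]
        preds.append(square_instance(10, x0=2, y0=40, side=4, confidence=0.9, source="predicted"))
        pred = _frame(preds)
        (m,) = class_metrics([match_instances(truth, pred)])
        assert (m.tp, m.fp) == (9, 1)
        assert m.specificity == pytest.approx(0.90)
        assert m.sensitivity == 1.0

    def test_all_matched_no_fp_gives_perfect_metrics(self):
        truth = _frame([square_instance(1, "pDC", 5, 5), square_instance(2, "pDC", 30, 30)])
        pred = _frame([
            square_instance(1, "pDC", 5, 5, confidence=0.9, source="predicted"),
            square_instance(2, "pDC", 30, 30, confidence=0.9, source="predicted"),
        ])
        (m,) = class_metrics([match_instances(truth, pred)])
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_missing_predictions_give_zero_sensitivity_and_flagged_ppv(self):
        truth = _frame([square_instance(i, "mDC", 6 * i, 2, 4) for i in range(1, 11)])
        (m,) = class_metrics([match_instances(truth, _frame([]))])
        assert m.sensitivity == 0.0 and m.fp == 0
        assert math.isnan(m.specificity)  # undefined, not silently zero

    def test_absent_class_reported_with_nan_not_dropped(self):
        ms = match_instances(_frame([]), _frame([]))
        (m,) = class_metrics([ms], classes=["Bcell"])
        assert m.n_truth == m.n_pred == 0
        assert math.isnan(m.sensitivity) and math.isnan(m.specificity)

    def test_weighted_overall_sensitivity(self):
        from immunoseg.evaluate import ClassMetrics

        a = ClassMetrics("CD4T", tp=10, fp=0, fn=0, n_truth=10, n_pred=10,
                         iou_mean=0.9, iou_sd=0.1)
        b = ClassMetrics("pDC", tp=72, fp=0, fn=18, n_truth=90, n_pred=72,
                         iou_mean=0.8, iou_sd=0.1)
        summary = overall_metrics([a, b])
        assert summary.sensitivity == pytest.approx(0.82)
        assert summary.sensitivity_unweighted == pytest.approx(0.9)
        assert min(a.sensitivity, b.sensitivity) <= summary.sensitivity <= max(
            a.sensitivity, b.sensitivity
        )

    def test_equal_class_sizes_weighted_equals_unweighted(self):
        from immunoseg.evaluate import ClassMetrics

        a = ClassMetrics("CD4T", tp=8, fp=2, fn=2, n_truth=10, n_pred=10,
                         iou_mean=0.9, iou_sd=0.1)
        b = ClassMetrics("pDC", tp=6, fp=4, fn=4, n_truth=10, n_pred=10,
                         iou_mean=0.7, iou_sd=0.1)
        summary = overall_metrics([a, b])
        assert summary.sensitivity == pytest.approx(summary.sensitivity_unweighted)

    def test_single_class_overall_equals_class_metrics(self):
        from immunoseg.evaluate import ClassMetrics

        a = ClassMetrics("CD4T", tp=7, fp=3, fn=1, n_truth=8, n_pred=10,
                         iou_mean=0.77, iou_sd=0.1)
        summary = overall_metrics([a])
        assert summary.sensitivity == pytest.approx(a.sensitivity)
        assert summary.specificity == pytest.approx(a.specificity)
        assert summary.iou_mean == pytest.approx(a.iou_mean)

    def test_all_empty_classes_raise(self):
        from immunoseg.evaluate import ClassMetrics

        empty = ClassMetrics("CD4T", 0, 0, 0, 0, 0, math.nan, math.nan)
        with pytest.raises(ValueError, match="empty"):
            overall_metrics([empty])


class TestCrossEvaluate:
    def test_truth_against_itself_is_perfect(self):
        truth_frames = [
            _frame([square_instance(1, "pDC", 5, 5), square_instance(2, "CD4T", 30, 30)], fid="a"),
            _frame([square_instance(1, "Bcell", 10, 40)], fid="b"),
        ]
        truth = CohortDataset(name="t", frames=truth_frames, role="truth")
        pred = CohortDataset(name="p", frames=truth_frames, role="predicted")
        summary = cross_evaluate(truth, pred)
        assert summary.sensitivity == 1.0
        assert summary.specificity == 1.0
        assert summary.iou_mean == 1.0

    def test_disjoint_frame_ids_listed_in_error(self):
        truth = CohortDataset(name="t", frames=[_frame([], fid="a")])
        pred = CohortDataset(name="p", frames=[_frame([], fid="b")], role="predicted")
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            cross_evaluate(truth, pred)

    def test_raising_tau_never_increases_prediction_count(self):
        rng = np.random.default_rng(15)
        frame = _frame([
            square_instance(i, x0=5 * i, y0=2, side=4,
                            confidence=float(rng.uniform(0.1, 1.0)), source="predicted")
            for i in range(1, 11)
        ])
        counts = [len(filter_confidence(frame, t).instances) for t in (0.0, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)
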