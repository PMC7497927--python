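"""Confusion counts, the five ×100-scale metrics, the subject-wise
detection rule and the leave-one-patient-out harness."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amcl.evaluation import (ConfusionCounts, MetricSet, confusion, metrics,
                             subject_wise_recall)


def _ms(recall):
    return MetricSet(specificity=99.0, accuracy=99.0, recall=recall,
                     precision=50.0, dice=50.0)


class TestConfusion:
    def test_all_negative_agreement(self):
        c = confusion(np.zeros((10, 10), bool), np.zeros((10, 10), bool))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 100)

    def test_complementary_masks(self, rng):
        truth = rng.random((12, 12)) > 0.5
        c = confusion(~truth, truth)
        assert c.tp == 0 and c.tn == 0
        assert c.fp + c.fn == truth.size

    def test_matches_per_pixel_loop(self, rng):
        pred = rng.random((16, 16)) > 0.6
        truth = rng.random((16, 16)) > 0.6
        c = confusion(pred, truth)
        tp = fp = tn = fn = 0
        for i in range(16):
            for j in range(16):
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_region_restriction(self, rng):
        pred = rng.random((10, 10)) > 0.5
        truth = rng.random((10, 10)) > 0.5
        region = np.zeros((10, 10), bool)
        region[:5] = True
        c = confusion(pred, truth, region)
        assert c.total == 50

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestMetrics:
    def test_recall_fifty(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=5))
        assert m.recall == pytest.approx(50.0)

    def test_dice_formula(self):
        m = metrics(ConfusionCounts(tp=10, fp=5, tn=0, fn=5))
        assert m.dice == pytest.approx(2 * 10 * 100 / (20 + 5 + 5))

    def test_perfect_prediction_scores_100_everywhere(self):
        m = metrics(ConfusionCounts(tp=40, fp=0, tn=60, fn=0))
        assert all(v == pytest.approx(100.0) for v in m.as_dict().values())

    def test_undefined_ratios_are_none_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert m.precision is None and m.recall is None
        assert m.specificity == pytest.approx(100.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_hand_computation_on_random_masks(self, rng):
        for _ in range(20):
            pred = rng.random((12, 12)) > 0.5
            truth = rng.random((12, 12)) > 0.5
            m = metrics(confusion(pred, truth))
            tp = int((pred & truth).sum())
            fp = int((pred & ~truth).sum())
            fn = int((~pred & truth).sum())
            tn = 144 - tp - fp - fn
            if tp + fn:
                assert m.recall == pytest.approx(100 * tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(100 * tn / (tn + fp))
            assert m.accuracy == pytest.approx(100 * (tp + tn) / 144)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    def test_dice_harmonic_identity(self, tp, fp, tn, fn):
        """Dice = 2·P·R/(P+R) on the 0–100 scale wherever defined."""
        if tp + fp + tn + fn == 0:
            return
        m = metrics(ConfusionCounts(tp, fp, tn, fn))
        if m.precision is None or m.recall is None or m.precision + m.recall == 0:
            return
        expected = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.dice == pytest.approx(expected, abs=1e-9)


class TestSubjectWise:
    def test_fifteen_of_eighteen_gives_8333(self):
        reports = [_ms(60.0)] * 15 + [_ms(5.0)] * 3
        assert subject_wise_recall(reports) == pytest.approx(83.33, abs=0.01)

    def test_all_sixteen_detected_gives_100(self):
        assert subject_wise_recall([_ms(30.0)] * 16) == pytest.approx(100.0)

    def test_recall_exactly_twenty_is_not_detected(self):
        assert subject_wise_recall([_ms(20.0)] * 5) == 0.0

    def test_images_without_lesion_truth_excluded_with_warning(self):
        reports = [_ms(50.0), _ms(None)]
        with pytest.warns(UserWarning):
            assert subject_wise_recall(reports) == pytest.approx(100.0)

    def test_no_valid_images_rejected(self):
        with pytest.raises(ValueError):
            subject_wise_recall([_ms(None)])


class TestLoocv:
    def test_one_fold_per_positive_patient(self, loocv_result, cohort):
        pos_patients = {i.patient_id for i, _ in cohort
                        if i.contrast_class == "positive"}
        per_patient_folds = [f for f in loocv_result["folds"]
                             if f["held_out"] is not None]
        assert len(per_patient_folds) == len(pos_patients)

    def test_no_fold_trains_on_its_test_patient(self, loocv_result):
        for fold in loocv_result["folds"]:
            if fold["held_out"] is not None:
                assert fold["held_out"] not in fold["train_patients"]

    def test_pooled_schema_covers_both_algorithms_and_classes(
            self, loocv_result):
        pooled = loocv_result["pooled"]
        for algo in ("amcl", "gradcam"):
            for cls in ("positive", "negative"):
                cell = pooled[algo][cls]
                assert {"subject_wise_recall", "specificity", "accuracy",
                        "recall", "precision", "dice"} <= set(cell)

    def test_visible_lesions_detected_at_least_as_often(self, loocv_result):
        pooled = loocv_result["pooled"]["amcl"]
        assert pooled["positive"]["subject_wise_recall"] >= \
            pooled["negative"]["subject_wise_recall"]

    def test_every_image_evaluated_once(self, loocv_result, cohort):
        assert len(loocv_result["per_image"]) == len(cohort)
        ids = [r["image_id"] for r in loocv_result["per_image"]]
        assert len(set(ids)) == len(ids)

    def test_too_few_positive_patients_rejected(self, cohort):
        from amcl.evaluation import loocv_evaluate
        small = [(i, l) for i, l in cohort if i.patient_id in ("P01", "P08")]
        with pytest.raises(ValueError):
            loocv_evaluate(small)
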