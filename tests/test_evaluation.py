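"""Metrics: confusion scalars, AUROC, image RMSE and SSIM.

The worked examples pin the implementation to the reference values of the
clinical study this toolkit models: the Finder confusion matrix
(TP 8994 / FP 4131 / TN 25383 / FN 3657), the detector metric table, and
the reconstruction quality summaries.
"""

import numpy as np
import pytest

from torsionlab.errors import InputError
from torsionlab.evaluation import (ConfusionMatrix, confusion_counts,
                                   image_rmse, image_ssim,
                                   metrics_from_confusion, roc_auc)

from helpers import auroc_pair_counting, confusion_tally_loop

# detector window-sweep reference rows: input time (s), recall,
# specificity, precision, accuracy, printed F1 (all percent)
SWEEP_TABLE = [
    (0.2, 87.13, 88.37, 89.74, 87.70, 88.42),
    (0.3, 89.99, 86.36, 87.67, 87.57, 88.82),
    (0.4, 88.97, 85.46, 87.61, 87.34, 88.28),
    (0.5, 82.81, 82.01, 84.59, 82.44, 83.69),
    (0.6, 78.30, 77.20, 79.56, 77.79, 78.93),
    (0.7, 78.00, 76.58, 78.80, 77.33, 78.40),
    (0.8, 78.15, 75.77, 78.26, 77.02, 78.20),
    (0.9, 77.93, 76.58, 78.79, 77.29, 78.36),
]


class TestConfusionCounts:
    def test_perfect_prediction(self):
        cm = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_inverted_prediction(self):
        truth = np.array([1, 0, 1, 0, 1])
        cm = confusion_counts(1 - truth, truth)
        assert cm.tp == 0 and cm.tn == 0
        assert cm.fp == 2 and cm.fn == 3

    def test_matches_tally_loop(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 200)
        truth = rng.integers(0, 2, 200)
        cm = confusion_counts(pred, truth)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == confusion_tally_loop(pred,
                                                                    truth)

    def test_non_binary_rejected(self):
        with pytest.raises(InputError):
            confusion_counts([0, 2], [0, 1])


class TestMetricsFromConfusion:
    def test_reference_confusion_matrix_scalars(self):
        """The published Finder evaluation: 42,165 frames."""
        cm = ConfusionMatrix(tp=8994, fp=4131, tn=25383, fn=3657)
        rep = metrics_from_confusion(cm)
        assert rep.accuracy * 100 == pytest.approx(81.53, abs=0.005)
        assert rep.sensitivity == pytest.approx(0.7109, abs=1e-4)
        assert rep.precision == pytest.approx(0.6852, abs=1e-4)
        assert rep.specificity == pytest.approx(0.8600, abs=1e-4)

    def test_all_correct_gives_ones(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert rep.sensitivity == rep.specificity == rep.precision == 1.0
        assert rep.accuracy == rep.f1 == 1.0

    @pytest.mark.parametrize(
        "time_s,recall,spec,prec,acc,f1", SWEEP_TABLE,
        ids=[f"{r[0]:.1f}s" for r in SWEEP_TABLE])
    def test_f1_consistent_with_printed_precision_recall(
            self, time_s, recall, spec, prec, acc, f1):
        # the printed precision/recall are rounded to 2 decimals, so the
        # recomputed F1 carries up to +-0.005 input error on top of the
        # printed F1's own rounding: one unit in the last digit overall
        p, r = prec / 100, recall / 100
        assert 100 * 2 * p * r / (p + r) == pytest.approx(f1, abs=0.01)

    def test_zero_denominator_reported_as_undefined(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, tn=4, fn=0))
        assert rep.precision is None and rep.sensitivity is None
        assert rep.f1 is None
        assert rep.specificity == 1.0

    def test_percent_conversion(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=1, fp=1, tn=1, fn=1))
        pct = rep.as_percent()
        assert pct["accuracy"] == pytest.approx(50.0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pair_counting_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.35, 0.7])
        labels = np.array([0, 0, 1, 1, 0, 1])
        assert roc_auc(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(5 * scores), labels) == pytest.approx(a)
        assert roc_auc(np.log(scores + 1e-9), labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.9], [1, 1])


class TestImageRmse:
    def test_identical_images_zero(self):
        img = np.random.default_rng(2).integers(0, 255, (32, 32))
        assert image_rmse(img, img) == 0.0

    def test_constant_offset(self):
        img = np.random.default_rng(3).integers(0, 245, (32, 32))
        assert image_rmse(img, img + 10) == pytest.approx(10.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 255, (2, 16, 16))
        assert image_rmse(a, b) == image_rmse(b, a)

    def test_per_class_mean_reproduces_summary(self):
        # published per-class reconstruction errors and their summary
        assert np.mean([28.38, 27.41]) == pytest.approx(27.895)
        assert 28.38 - 27.41 == pytest.approx(0.97)


class TestImageSsim:
    def test_identical_images_one(self):
        img = np.random.default_rng(5).integers(0, 255, (64, 64)).astype(float)
        assert image_ssim(img, img) == pytest.approx(1.0)

    def test_negated_image_is_anticorrelated(self):
        rng = np.random.default_rng(6)
        img = (128 + 60 * rng.normal(size=(64, 64))).clip(0, 255)
        assert image_ssim(img, 255 - img) < 0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = (128 + 40 * rng.normal(size=(64, 64))).clip(0, 255)
        b = (128 + 40 * rng.normal(size=(64, 64))).clip(0, 255)
        assert image_ssim(a, b) == pytest.approx(image_ssim(b, a))

    def test_per_class_mean_reproduces_summary(self):
        assert np.mean([0.9208, 0.9320]) == pytest.approx(0.9264)
        assert 0.9320 - 0.9208 == pytest.approx(0.0112)
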