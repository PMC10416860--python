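"""Classifier plumbing, foveal ROI localization and the evaluation metrics,
including reference worked examples for a 30-image test set."""

import numpy as np
import pytest

from octdme.classification import (
    ClassifierConfig,
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    build_classifier,
    classify_dril,
    confusion_counts,
    evaluation_report,
    f1,
    load_classifier,
    locate_foveal_roi,
    precision,
    preprocess_classifier_input,
    save_classifier,
    sensitivity,
    specificity,
    train_classifier,
)
from octdme.phantom import default_phantom_spec, generate_phantom


class TestPreprocess:
    def test_uniform_gray_scales_by_255(self):
        img = np.full((50, 60, 3), 128, dtype=np.uint8)
        out = preprocess_classifier_input(img, 64)
        assert out.shape == (64, 64)
        assert out.mean() == pytest.approx(128 / 255, abs=1e-3)

    def test_output_range_and_resize(self, rng):
        img = (rng.random((100, 200)) * 255).astype(np.uint8)
        out = preprocess_classifier_input(img, 416)
        assert out.shape == (416, 416)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_classifier_input(np.empty((0, 0)), 64)


class TestConfusionCounts:
    def test_perfect_split(self):
        pred = ["p"] * 8 + ["n"] * 8
        c = confusion_counts(pred, pred, "p")
        assert (c.tp, c.tn, c.fp, c.fn) == (8, 8, 0, 0)

    def test_flipping_predictions_swaps_counts(self):
        truth = ["p", "p", "n", "n", "p"]
        pred = ["p", "n", "n", "p", "p"]
        flipped = ["n" if p == "p" else "p" for p in pred]
        a = confusion_counts(pred, truth, "p")
        b = confusion_counts(flipped, truth, "p")
        assert (a.tp, a.fn) == (b.fn, b.tp) and (a.tn, a.fp) == (b.fp, b.tn)

    def test_matches_bruteforce_enumeration(self, rng):
        truth = list(rng.choice(["p", "n"], 20))
        pred = list(rng.choice(["p", "n"], 20))
        c = confusion_counts(pred, truth, "p")
        pairs = list(zip(pred, truth))
        assert c.tp == sum(1 for p, t in pairs if p == t == "p")
        assert c.tn == sum(1 for p, t in pairs if p == t == "n")
        assert c.fp == sum(1 for p, t in pairs if p == "p" and t == "n")
        assert c.fn == sum(1 for p, t in pairs if p == "n" and t == "p")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["p"], ["p", "n"], "p")


class TestMetrics:
    def test_dril_normal_worked_example(self):
        """30 test scans: sensitivity 0.875 and specificity 1.0 imply
        TP=14, FP=0, FN=2, TN=14; accuracy and F1 follow."""
        c = ConfusionCounts(tp=14, fp=0, fn=2, tn=14)
        assert sensitivity(c) == pytest.approx(0.875, abs=5e-5)
        assert specificity(c) == pytest.approx(1.0, abs=5e-5)
        assert accuracy(c) == pytest.approx(0.9333, abs=5e-5)
        assert f1(c) == pytest.approx(0.93333, abs=5e-6)

    def test_centrality_worked_example(self):
        c = ConfusionCounts(tp=14, fp=2, fn=1, tn=13)
        assert sensitivity(c) == pytest.approx(0.9333, abs=5e-5)
        assert specificity(c) == pytest.approx(0.8666, abs=1e-4)
        assert accuracy(c) == pytest.approx(0.90, abs=5e-5)
        assert f1(c) == pytest.approx(0.9032, abs=5e-5)

    def test_perfect_classifier_all_ones(self):
        c = ConfusionCounts(tp=10, fp=0, fn=0, tn=10)
        for metric in (sensitivity, precision, specificity, f1, accuracy):
            assert metric(c) == 1.0

    def test_accuracy_is_prevalence_weighted_mix(self, rng):
        for _ in range(20):
            c = ConfusionCounts(*(int(x) for x in rng.integers(1, 30, size=4)))
            npos, nneg = c.tp + c.fn, c.tn + c.fp
            mix = (npos * sensitivity(c) + nneg * specificity(c)) / (npos + nneg)
            assert accuracy(c) == pytest.approx(mix)

    def test_f1_between_precision_and_sensitivity(self, rng):
        for _ in range(20):
            c = ConfusionCounts(*(int(x) for x in rng.integers(1, 30, size=4)))
            lo, hi = sorted([precision(c), sensitivity(c)])
            assert lo - 1e-12 <= f1(c) <= hi + 1e-12

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(tp=0, fp=1, fn=0, tn=1))
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(tp=0, fp=0, fn=1, tn=1))

    def test_report_structure(self):
        rep = evaluation_report(ConfusionCounts(14, 0, 2, 14))
        assert set(rep) == {"counts", "sensitivity", "specificity", "precision", "f1", "accuracy"}


class TestFovealROI:
    @pytest.mark.parametrize("fovea_col", [60, 96, 130])
    def test_detects_fovea_within_3px(self, fovea_col):
        b = generate_phantom(default_phantom_spec(fovea_col=fovea_col))
        roi = locate_foveal_roi(b.image, um_per_px=11.7)
        assert abs(roi.col_center - fovea_col) <= 3

    def test_width_matches_calibration(self):
        b = generate_phantom(default_phantom_spec())
        for um in (10.0, 11.7, 20.0):
            roi = locate_foveal_roi(b.image, um_per_px=um)
            assert roi.width_px == round(1000.0 / um)

    def test_translation_equivariance(self):
        img = generate_phantom(default_phantom_spec(fovea_col=96)).image
        base = locate_foveal_roi(img, um_per_px=11.7).col_center
        for k in (-20, 15):
            shifted = locate_foveal_roi(np.roll(img, k, axis=1), um_per_px=11.7).col_center
            assert abs((shifted - base) - k) <= 1

    def test_no_band_detected(self):
        with pytest.raises(ValueError, match="retinal band"):
            locate_foveal_roi(np.zeros((64, 64)), um_per_px=11.7)


class TestTraining:
    def _tiny_setup(self):
        cfg = ClassifierConfig(input_size=64, epochs=2, batch_size=2, seed=0)
        rng = np.random.default_rng(0)
        images = [rng.random((64, 64)).astype(np.float32) for _ in range(6)]
        labels = [0, 1, 0, 1, 0, 1]
        return cfg, images, labels

    def test_untrained_model_refuses_to_classify(self):
        cfg, images, _ = self._tiny_setup()
        model = build_classifier(cfg)
        with pytest.raises(RuntimeError, match="not been trained"):
            classify_dril(model, images[0])

    def test_same_seed_reproduces_history(self):
        cfg, images, labels = self._tiny_setup()
        h1 = train_classifier(build_classifier(cfg), images, labels, cfg)
        h2 = train_classifier(build_classifier(cfg), images, labels, cfg)
        assert h1 == h2

    def test_probabilities_sum_to_one_and_label_deterministic(self):
        cfg, images, labels = self._tiny_setup()
        model = build_classifier(cfg)
        train_classifier(model, images, labels, cfg)
        label1, p1 = classify_dril(model, images[0])
        label2, p2 = classify_dril(model, images[0])
        assert label1 == label2 and p1 == p2
        assert 0.5 <= p1 <= 1.0  # argmax probability of a 2-way softmax

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg, images, labels = self._tiny_setup()
        model = build_classifier(cfg)
        train_classifier(model, images, labels, cfg)
        save_classifier(model, tmp_path / "clf.npz")
        loaded = load_classifier(tmp_path / "clf.npz")
        assert classify_dril(loaded, images[0]) == classify_dril(model, images[0])
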