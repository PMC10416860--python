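"""Desk-scale training recipes shared by the CLI, the examples and the
acceptance checks.

These wire the phantom generator to the segmentation and classification
trainers at sizes that run in minutes on one CPU core: 192 px phantoms for
segmentation, 416 px phantoms for DRIL classification. All randomness is
driven by the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .classification import (
    ClassifierConfig,
    build_classifier,
    classify_dril,
    classify_dril_centrality,
    locate_foveal_roi,
    train_classifier,
)
from .phantom import default_phantom_spec, generate_dataset
from .segmentation import UNetConfig, build_unet, dsc_hard, predict_mask, train_segmenter

__all__ = [
    "segmentation_phantoms",
    "classification_phantoms",
    "train_segmenter_on_phantoms",
    "train_dril_classifier_on_phantoms",
    "train_centrality_classifier_on_phantoms",
]


def segmentation_phantoms(n: int, seed: int, size: int = 192, um_per_px: float | None = None):
    """Phantoms with guaranteed cystoids and a spread of HRFs, for training
    the segmentation networks."""
    over = {} if um_per_px is None else {"um_per_px": um_per_px}
    base = default_phantom_spec(size, size, **over)
    return generate_dataset(
        n, {"normal": 0.5, "dril": 0.5}, base_spec=base, seed=seed, hrf_range=(1, 5), cystoid_range=(1, 3)
    )


def classification_phantoms(n: int, seed: int, size: int = 416, um_per_px: float | None = None):
    """Balanced DRIL/normal phantoms at the classifier's working resolution."""
    over = {} if um_per_px is None else {"um_per_px": um_per_px}
    base = default_phantom_spec(size, size, **over)
    return generate_dataset(n, {"dril": 0.5, "normal": 0.5}, base_spec=base, seed=seed)


def train_segmenter_on_phantoms(
    target: str,
    n_train: int = 20,
    n_test: int = 5,
    config: UNetConfig | None = None,
    seed: int = 0,
):
    """Train a U-Net for one target and score held-out phantoms with hard DSC.

    Returns (model, history, mean held-out DSC)."""
    if config is None:
        config = UNetConfig(seed=seed)
    bundles = segmentation_phantoms(n_train + n_test, seed=seed, size=config.input_size)
    train, test = bundles[:n_train], bundles[n_train:]
    model = build_unet(config)
    history = train_segmenter(model, train, target, config)
    scores = [
        dsc_hard(predict_mask(model, b.image, target=target), getattr(b, f"{target}_mask")) for b in test
    ]
    return model, history, float(np.mean(scores)) if scores else float("nan")


def _fit_with_restarts(images, labels, config: ClassifierConfig, max_restarts: int = 2, min_train_acc: float = 0.95):
    """Train; if the optimizer lands in a poor basin (training accuracy below
    ``min_train_acc``), reinitialize with a derived seed and try again. The
    decision uses training data only and is deterministic in the seed."""
    import dataclasses as _dc

    best = None
    for attempt in range(max_restarts + 1):
        cfg = _dc.replace(config, seed=config.seed + 101 * attempt)
        model = build_classifier(cfg)
        history = train_classifier(model, images, labels, cfg)
        acc = history[-1]["accuracy"]
        if best is None or acc > best[2]:
            best = (model, history, acc)
        if acc >= min_train_acc:
            break
    return best[0], best[1]


def train_dril_classifier_on_phantoms(
    n_train: int = 100,
    n_test: int = 30,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    phantom_size: int | None = None,
):
    """Train the DRIL/normal classifier and report held-out accuracy.

    Desk-scale defaults: 128 px phantoms (pixel pitch scaled so the retina
    occupies the same fraction of the frame as at 192 px / 11.7 um) and the
    study's 100-train / 30-test split.

    Returns (model, history, accuracy, (pred_labels, true_labels))."""
    if config is None:
        config = ClassifierConfig(input_size=128, epochs=20, seed=seed)
    size = phantom_size or config.input_size
    um = 11.7 * 192.0 / size
    bundles = classification_phantoms(n_train + n_test, seed=seed, size=size, um_per_px=um)
    train, test = bundles[:n_train], bundles[n_train:]
    labels = [1 if b.dril_label == "dril" else 0 for b in train]
    model, history = _fit_with_restarts([b.image for b in train], labels, config)
    preds = [classify_dril(model, b.image)[0] for b in test]
    truths = [b.dril_label for b in test]
    acc = float(np.mean([p == t for p, t in zip(preds, truths)])) if test else float("nan")
    return model, history, acc, (preds, truths)


def train_centrality_classifier_on_phantoms(
    n_train: int = 60,
    n_test: int = 20,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    phantom_size: int = 192,
):
    """Train the central/non-central classifier on foveal-ROI crops.

    Returns (model, history, accuracy)."""
    if config is None:
        config = ClassifierConfig(input_size=128, epochs=20, seed=seed)
    base = default_phantom_spec(phantom_size, phantom_size, um_per_px=11.7 * 192.0 / phantom_size)
    bundles = generate_dataset(
        n_train + n_test,
        {"dril_central": 0.5, "dril_non_central": 0.5},
        base_spec=base,
        seed=seed,
    )
    train, test = bundles[:n_train], bundles[n_train:]

    def crop(b):
        roi = locate_foveal_roi(b.image, um_per_px=b.spec.um_per_px)
        r0, c0, r1, c1 = roi.box
        return b.image[r0:r1, c0:c1]

    labels = [1 if b.dril_centrality == "central" else 0 for b in train]
    model, history = _fit_with_restarts([crop(b) for b in train], labels, config)
    correct = 0
    for b in test:
        roi = locate_foveal_roi(b.image, um_per_px=b.spec.um_per_px)
        pred = classify_dril_centrality(model, b.image, roi)
        correct += pred == b.dril_centrality
    acc = correct / len(test) if test else float("nan")
    return model, history, acc
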