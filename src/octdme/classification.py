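"""DRIL presence and centrality classification, foveal ROI localization,
and the confusion-matrix evaluation metrics.

The DRIL classifier sees a grayscale scan resized to a square input with
pixel values scaled by 1/255; softmax over two classes gives the DRIL
probability. The foveal region of interest is a window whose width
corresponds to 1 mm at the active calibration; the default localizer finds
the foveal depression as the column of minimum smoothed retinal-band
thickness, replacing a learned detector with a deterministic geometric one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

from .nn import Adam, build_backbone

__all__ = [
    "ClassifierConfig",
    "FovealROI",
    "ConfusionCounts",
    "UndefinedMetricError",
    "preprocess_classifier_input",
    "texture_stem",
    "build_classifier",
    "train_classifier",
    "classify_dril",
    "classify_dril_centrality",
    "locate_foveal_roi",
    "confusion_counts",
    "sensitivity",
    "precision",
    "f1",
    "accuracy",
    "specificity",
    "evaluation_report",
    "save_classifier",
    "load_classifier",
]

DRIL_CLASSES = ("normal", "dril")
CENTRALITY_CLASSES = ("non_central", "central")


@dataclass
class ClassifierConfig:
    input_size: int = 416
    channels: int = 1
    backbone: str = "small_cnn"
    epochs: int = 75
    learning_rate: float = 2e-3
    batch_size: int = 4
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.input_size <= 0:
            raise ValueError("input_size must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FovealROI:
    col_center: int
    width_px: int
    box: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), exclusive max


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


def preprocess_classifier_input(image, input_size: int = 416) -> np.ndarray:
    """Grayscale, resize to (input_size, input_size), scale to [0, 1]."""
    if isinstance(image, (str, Path)):
        image = np.asarray(Image.open(image))
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    img = img.astype(np.float32)
    if img.ndim == 3:
        img = img.mean(axis=2)
    elif img.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")
    if img.max() > 1.0:
        img = img / 255.0
    if img.shape != (input_size, input_size):
        img = resize(img, (input_size, input_size), order=1, preserve_range=True, anti_aliasing=True)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def texture_stem(image: np.ndarray) -> np.ndarray:
    """Stack the image with local-contrast maps at two scales.

    Local standard deviation over windows of roughly 1/18 and 1/6 of the
    image side makes texture disruptions (such as locally erased retinal
    layering) directly visible to the first convolution; the maps are fixed,
    not learned."""
    img = np.asarray(image, dtype=np.float32)
    side = img.shape[0]
    chans = [img]
    for divisor in (18, 6):
        k = max(3, 2 * round(side / (2 * divisor)) + 1)
        m = ndimage.uniform_filter(img, k)
        m2 = ndimage.uniform_filter(img * img, k)
        chans.append(np.sqrt(np.maximum(m2 - m * m, 0.0)))
    return np.stack(chans)


def build_classifier(config: ClassifierConfig):
    # the network sees the grayscale image plus the two stem channels
    model = build_backbone(config.backbone, config.input_size, config.channels + 2, config.seed, config.dropout_rate)
    model.config = config
    return model


def _softmax_ce_grad(logits: np.ndarray, labels: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(np.float32)


def train_classifier(model, images, labels, config: ClassifierConfig | None = None):
    """Train a softmax classifier on preprocessed images with integer labels.

    Returns per-epoch history of (epoch, loss, accuracy) on the training set.
    """
    if config is None:
        config = model.config
    images = [preprocess_classifier_input(im, config.input_size) for im in images]
    if len(images) < 2:
        raise ValueError("need at least 2 training images")
    x = np.stack([texture_stem(im) for im in images])  # N,3,H,W
    y = np.asarray(labels, dtype=np.int64)
    if len(y) != len(x):
        raise ValueError("images and labels length mismatch")
    opt = Adam(model.params(), model.grads(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = []
    n = len(x)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z = model.forward(x[idx], train=True)
            loss, gz = _softmax_ce_grad(z, y[idx])
            losses.append(loss)
            correct += int((z.argmax(axis=1) == y[idx]).sum())
            model.backward(gz)
            opt.step()
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n})
    model.trained = True
    return history


def _predict(model, image) -> np.ndarray:
    if not getattr(model, "trained", False):
        raise RuntimeError("classifier has not been trained")
    x = texture_stem(preprocess_classifier_input(image, model.config.input_size))[None]
    return model.predict_proba(x)[0]


def classify_dril(model, image) -> tuple[str, float]:
    """-> (label in {'normal','dril'}, probability of the chosen label)."""
    probs = _predict(model, image)
    k = int(probs.argmax())
    return DRIL_CLASSES[k], float(probs[k])


def locate_foveal_roi(image, strategy: str = "profile", um_per_px: float = 11.7) -> FovealROI:
    """Find the 1 mm central foveal window.

    'profile' strategy: threshold the smoothed scan to the retinal band and
    take the column of minimum band thickness (the foveal depression).
    """
    if strategy != "profile":
        raise NotImplementedError(f"strategy {strategy!r} not available; use 'profile'")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    h, w = img.shape
    smoothed = ndimage.gaussian_filter(img, sigma=2.0)
    thresh = 0.5 * (smoothed.min() + smoothed.max())
    band = smoothed > thresh
    thickness = band.sum(axis=0).astype(float)
    if thickness.max() < 3:
        raise ValueError("no retinal band detected: thresholded image is almost empty")
    # ignore columns with no band at all (e.g. letterbox padding)
    thickness[thickness == 0] = np.inf
    profile = ndimage.uniform_filter1d(np.where(np.isfinite(thickness), thickness, np.nan), size=9, mode="nearest")
    profile = np.where(np.isnan(profile), np.inf, profile)
    col_center = int(np.argmin(profile))
    width_px = round(1000.0 / um_per_px)
    c0 = max(0, col_center - width_px // 2)
    c1 = min(w, c0 + width_px)
    c0 = max(0, c1 - width_px)
    return FovealROI(col_center=col_center, width_px=width_px, box=(0, c0, h, c1))


def classify_dril_centrality(model, image, roi: FovealROI) -> str:
    """Classify the ROI crop as 'central' or 'non_central' DRIL."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    r0, c0, r1, c1 = roi.box
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValueError(f"ROI box {roi.box} outside image of shape {img.shape}")
    crop = img[r0:r1, c0:c1]
    probs = _predict(model, crop)
    return CENTRALITY_CLASSES[int(probs.argmax())]


# -- evaluation metrics --------------------------------------------------


def confusion_counts(pred_labels, true_labels, positive_label) -> ConfusionCounts:
    pred_labels, true_labels = list(pred_labels), list(true_labels)
    if len(pred_labels) != len(true_labels):
        raise ValueError("label lists must have equal length")
    tp = fp = fn = tn = 0
    for p, t in zip(pred_labels, true_labels):
        if t == positive_label:
            tp += p == positive_label
            fn += p != positive_label
        else:
            fp += p == positive_label
            tn += p != positive_label
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num, denom, name):
    if denom == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / denom


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def f1(c: ConfusionCounts) -> float:
    p, s = precision(c), sensitivity(c)
    return _ratio(2.0 * p * s, p + s, "f1")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def evaluation_report(c: ConfusionCounts) -> dict:
    return {
        "counts": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "precision": precision(c),
        "f1": f1(c),
        "accuracy": accuracy(c),
    }


# -- persistence ---------------------------------------------------------


def save_classifier(model, path: str | Path) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    cfg = asdict(model.config)
    cfg["trained"] = bool(getattr(model, "trained", False))
    np.savez(Path(path), __config__=json.dumps(cfg), **arrays)


def load_classifier(path: str | Path):
    data = np.load(Path(path), allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    trained = cfg.pop("trained", False)
    config = ClassifierConfig(**cfg)
    model = build_classifier(config)
    for i, p in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    model.trained = trained
    return model
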