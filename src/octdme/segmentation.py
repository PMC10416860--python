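"""Semantic segmentation of HRF, OPL and cystoid spaces.

The training objective combines pixel-mean binary cross-entropy with the
Dice similarity coefficient:

    loss = w * BCE(y, p) - DSC(y, p),        w = 0.3 by default

where the Dice term inside the loss is the *soft* (differentiable) form
(2*sum(p*y) + s) / (sum(p) + sum(y) + s) with smoothing s = 1, while
evaluation uses the set-based (hard) DSC on thresholded masks. A perfect
prediction drives the loss to its lower bound of -1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .nn import Adam, UNet

__all__ = [
    "EPS",
    "SMOOTH",
    "UNetConfig",
    "bce",
    "soft_dice",
    "dsc_hard",
    "custom_loss",
    "build_unet",
    "train_segmenter",
    "predict_mask",
    "gaussian_blur5",
    "save_model",
    "load_model",
    "history_to_csv",
]

EPS = 1e-7  # probability clip
SMOOTH = 1.0  # soft-Dice smoothing


@dataclass
class UNetConfig:
    input_size: int = 192
    input_channels: int = 3
    base_filters: int = 8
    depth: int = 3
    dropout_rate: float = 0.1
    learning_rate: float = 3e-3
    epochs: int = 30
    batch_size: int = 2
    seed: int = 0
    binarization_threshold: float = 0.5
    bce_weight: float = 0.3

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.input_size % 2**self.depth:
            raise ValueError("input_size must be divisible by 2^depth")


def _pair(prob, truth):
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {truth.shape}")
    return prob, truth


def bce(prob: np.ndarray, truth: np.ndarray) -> float:
    """Pixel-mean binary cross-entropy with probabilities clipped to [EPS, 1-EPS]."""
    prob, truth = _pair(prob, truth)
    p = np.clip(prob, EPS, 1.0 - EPS)
    return float(-(truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p)).mean())


def soft_dice(prob: np.ndarray, truth: np.ndarray) -> float:
    """Differentiable Dice: (2*sum(p*y)+s)/(sum(p)+sum(y)+s)."""
    prob, truth = _pair(prob, truth)
    return float((2.0 * (prob * truth).sum() + SMOOTH) / (prob.sum() + truth.sum() + SMOOTH))


def dsc_hard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Set-based Dice similarity 2|A∩B|/(|A|+|B|); 1.0 when both are empty."""
    pred, truth = _pair(pred, truth)
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred * truth).sum() / denom)


def custom_loss(prob: np.ndarray, truth: np.ndarray, bce_weight: float = 0.3) -> float:
    """bce_weight * BCE - soft Dice; bounded below by -1."""
    return bce_weight * bce(prob, truth) - soft_dice(prob, truth)


def _loss_grad_wrt_logits(prob, truth, bce_weight):
    """d(custom_loss)/d(logits) for prob = sigmoid(logits)."""
    n = prob.size
    g_bce = (prob - truth) / n
    denom = prob.sum() + truth.sum() + SMOOTH
    num = 2.0 * (prob * truth).sum() + SMOOTH
    g_dice_p = (2.0 * truth * denom - num) / denom**2
    g_dice = g_dice_p * prob * (1.0 - prob)
    return (bce_weight * g_bce - g_dice).astype(np.float32)


def build_unet(config: UNetConfig) -> UNet:
    """Instantiate the U-Net for the configured input geometry."""
    model = UNet(
        input_channels=config.input_channels,
        base_filters=config.base_filters,
        depth=config.depth,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
    )
    model.config = config
    return model


def gaussian_blur5(image: np.ndarray) -> np.ndarray:
    """5x5 Gaussian denoising blur (sigma 1.1, radius-2 kernel)."""
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float32), sigma=1.1, truncate=1.82, mode="nearest")


def _prepare_input(image: np.ndarray, config: UNetConfig, blur: bool) -> np.ndarray:
    """-> (C, H, W) float32 at the model input size."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if blur:
        img = gaussian_blur5(img)
    s = config.input_size
    if img.shape != (s, s):
        img = resize(img, (s, s), order=1, preserve_range=True, anti_aliasing=True).astype(np.float32)
    return np.repeat(img[None], config.input_channels, axis=0)


def _prepare_target(mask: np.ndarray, config: UNetConfig) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float32)
    s = config.input_size
    if m.shape != (s, s):
        m = (resize(m, (s, s), order=0, preserve_range=True) > 0.5).astype(np.float32)
    return m[None]


def train_segmenter(model: UNet, bundles, target: str, config: UNetConfig):
    """Train on phantom bundles for one target in {'hrf', 'opl', 'cystoid'}.

    Returns a history list of dicts (epoch, loss, soft_dice). The model is
    updated in place with Adam on the composite BCE/Dice loss; cystoid
    inputs are blurred first, matching inference.
    """
    if target not in ("hrf", "opl", "cystoid"):
        raise ValueError(f"unknown target {target!r}")
    bundles = list(bundles)
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles to train")
    blur = target == "cystoid"
    x = np.stack([_prepare_input(b.image, config, blur) for b in bundles])
    y = np.stack([_prepare_target(getattr(b, f"{target}_mask"), config) for b in bundles])
    opt = Adam(model.params(), model.grads(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = []
    n = len(bundles)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses, dices = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            z = model.forward(xb, train=True)
            p = 1.0 / (1.0 + np.exp(-np.clip(z.astype(np.float64), -60.0, 60.0)))
            losses.append(custom_loss(p, yb, config.bce_weight))
            dices.append(soft_dice(p, yb))
            model.backward(_loss_grad_wrt_logits(p, yb, config.bce_weight))
            opt.step()
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "soft_dice": float(np.mean(dices))})
        if not np.isfinite(history[-1]["loss"]):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
    model.trained_target = target
    return history


def predict_mask(model: UNet, image: np.ndarray, threshold: float | None = None, target: str | None = None) -> np.ndarray:
    """Binarize the sigmoid output at ``threshold`` (default from config).

    For cystoid segmentation a 5x5 Gaussian blur is applied to the input
    first, matching the training-time preprocessing.
    """
    config: UNetConfig = model.config
    if threshold is None:
        threshold = config.binarization_threshold
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if target is None:
        target = getattr(model, "trained_target", None)
    blur = target == "cystoid"
    xb = _prepare_input(image, config, blur)[None]
    prob = model.predict_proba(xb)[0, 0]
    return (prob >= threshold).astype(np.uint8)


# -- persistence ---------------------------------------------------------


def save_model(model: UNet, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    cfg = asdict(model.config)
    cfg["trained_target"] = getattr(model, "trained_target", None)
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_model(path: str | Path) -> UNet:
    data = np.load(Path(path), allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    target = cfg.pop("trained_target", None)
    config = UNetConfig(**cfg)
    model = build_unet(config)
    for i, p in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    if target:
        model.trained_target = target
    return model


def history_to_csv(history, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["epoch", "loss", "soft_dice"])
        wr.writeheader()
        wr.writerows(history)
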