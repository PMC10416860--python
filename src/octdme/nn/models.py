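"""Network architectures: the segmentation U-Net and the classifier backbones.

The U-Net follows the standard encoder/decoder layout: 3x3 convolutions with
ReLU and dropout after each convolution block, 2x2 stride-2 max-pooling on the
contracting path, nearest-neighbour up-sampling with concatenation of the
mirrored encoder feature map on the expanding path, and a final 1x1
convolution to a single channel read through a sigmoid.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GlobalAveragePool,
    GlobalMaxPool,
    Layer,
    MaxPool2,
    ReLU,
    Upsample2,
)

__all__ = ["Sequential", "UNet", "SmallCNN", "VGG19Classifier", "build_backbone"]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


def _conv_block(in_ch: int, out_ch: int, n_convs: int, dropout: float, rng) -> Sequential:
    layers: list[Layer] = []
    ch = in_ch
    for _ in range(n_convs):
        layers += [Conv2D(ch, out_ch, 3, rng), ReLU(), Dropout(dropout, rng)]
        ch = out_ch
    return Sequential(layers)


class UNet:
    """Fully convolutional encoder/decoder producing one sigmoid channel."""

    def __init__(
        self,
        input_channels: int = 3,
        base_filters: int = 8,
        depth: int = 3,
        dropout_rate: float = 0.1,
        seed: int = 0,
    ):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_filters = base_filters
        f = base_filters
        self.enc: list[Sequential] = []
        self.pools: list[MaxPool2] = []
        ch = input_channels
        for i in range(depth):
            self.enc.append(_conv_block(ch, f * 2**i, 2, dropout_rate, rng))
            self.pools.append(MaxPool2())
            ch = f * 2**i
        self.bott = _conv_block(ch, f * 2**depth, 2, dropout_rate, rng)
        self.up: list[Sequential] = []
        self.dec: list[Sequential] = []
        ch = f * 2**depth
        for i in reversed(range(depth)):
            self.up.append(Sequential([Upsample2(), Conv2D(ch, f * 2**i, 3, rng), ReLU()]))
            self.dec.append(_conv_block(2 * f * 2**i, f * 2**i, 1, dropout_rate, rng))
            ch = f * 2**i
        self.head = Conv2D(f, 1, 1, rng)
        self._modules = self.enc + [self.bott] + self.up + self.dec + [self.head]

    def params(self):
        return [p for m in self._modules for p in m.params()]

    def grads(self):
        return [g for m in self._modules for g in m.grads()]

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, H, W) -> logits (N, 1, H, W). H and W must divide 2**depth."""
        n, c, h, w = x.shape
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(f"input size {h}x{w} not divisible by 2^{self.depth}")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bott.forward(x, train)
        self._split = []
        for j, i in enumerate(reversed(range(self.depth))):
            x = self.up[j].forward(x, train)
            skip = skips[i]
            self._split.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self.dec[j].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, gz: np.ndarray) -> None:
        g = self.head.backward(gz)
        gskips: dict[int, np.ndarray] = {}
        for j, i in zip(reversed(range(self.depth)), range(self.depth)):
            g = self.dec[j].backward(g)
            nskip = self._split[j]
            gskips[i] = g[:, :nskip]
            g = self.up[j].backward(g[:, nskip:])
        g = self.bott.backward(g)
        for i in reversed(range(self.depth)):
            g = self.pools[i].backward(g)
            g = g + gskips[i]
            g = self.enc[i].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = np.clip(self.forward(x, train=False), -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(-z))


class _ClassifierBase:
    """Shared plumbing for softmax classifiers built on Sequential stacks."""

    net: Sequential
    trained: bool = False

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def backward(self, gy):
        return self.net.backward(gy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.net.forward(x, train=False)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class SmallCNN(_ClassifierBase):
    """Three conv/pool blocks, a global max pool and a softmax head.

    The global max pool makes the decision translation-invariant — the model
    asks whether a texture (e.g. locally erased layering) occurs anywhere,
    which is the right bias for lesion-presence classification and lets a
    few dozen training images generalize."""

    def __init__(
        self,
        input_size: int = 416,
        channels: int = 1,
        n_classes: int = 2,
        seed: int = 0,
        dropout_rate: float = 0.2,
    ):
        if input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        rng = np.random.default_rng(seed)
        drng = np.random.default_rng(seed + 1000)
        layers: list[Layer] = []
        ch = channels
        for wdt, npool in ((8, 2), (16, 2), (32, 1)):
            layers += [Conv2D(ch, wdt, 3, rng), ReLU(), Dropout(dropout_rate, drng)]
            layers += [MaxPool2() for _ in range(npool)]
            ch = wdt
        layers += [
            Conv2D(ch, 32, 3, rng),
            ReLU(),
            Dropout(dropout_rate, drng),
            GlobalMaxPool(),
            Dense(32, n_classes, rng),
        ]
        self.net = Sequential(layers)
        self.input_size = input_size
        self.channels = channels


_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M", 512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


class VGG19Classifier(_ClassifierBase):
    """VGG-19 convolutional topology (3x3 convs, 2x2 pools) with a compact
    global-average-pool head instead of the original 4096-wide dense stack.
    Provided untrained; no ImageNet weights are shipped."""

    def __init__(self, input_size: int = 416, channels: int = 1, n_classes: int = 2, seed: int = 0):
        if input_size % 32:
            raise ValueError("input_size must be divisible by 32 for VGG-19")
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        ch = channels
        for item in _VGG19_CFG:
            if item == "M":
                layers.append(MaxPool2())
            else:
                layers += [Conv2D(ch, item, 3, rng), ReLU()]
                ch = item
        layers += [GlobalAveragePool(), Dense(ch, n_classes, rng)]
        self.net = Sequential(layers)
        self.input_size = input_size
        self.channels = channels


def build_backbone(name: str, input_size: int, channels: int = 1, seed: int = 0, dropout_rate: float = 0.2):
    if name == "small_cnn":
        return SmallCNN(input_size, channels, seed=seed, dropout_rate=dropout_rate)
    if name == "vgg19":
        return VGG19Classifier(input_size, channels, seed=seed)
    raise ValueError(f"unknown backbone {name!r}; expected 'small_cnn' or 'vgg19'")
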