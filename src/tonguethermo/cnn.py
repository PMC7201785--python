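"""VGG-style convolutional network for thermogram classification.

A compact, dependency-free implementation of the convolutional classifier
stage: stacked blocks of 3x3 same-padding convolutions with ReLU followed by
2x2 max pooling, a fully connected ReLU layer, and a softmax head, trained
with plain stochastic gradient descent (default learning rate 0.01) on
softmax cross-entropy.  The block structure is configurable: the default is
a down-scaled two-block network suitable for CPU-scale experiments on small
synthetic thermograms, and :meth:`CNNConfig.vgg16` reproduces the full
five-block/thirteen-convolution topology.  Training-fold augmentation
(shear, zoom, rotation, horizontal flip, translation) is applied on the fly.

The final dense layer is zero-initialized with class-prior biases, so an
untrained (zero-epoch) network predicts the empirical priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classify import POSITIVE, NEGATIVE

__all__ = ["CNNConfig", "CNNClassifier", "fit_cnn"]

AUGMENTATIONS = ("shear", "zoom", "rotation", "hflip", "translation")


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training settings.

    ``blocks`` lists (filters, conv-layers) per block; every block ends in
    2x2 max pooling, halving the spatial size.
    """

    input_size: int = 32
    channels: int = 1
    blocks: tuple[tuple[int, int], ...] = ((8, 1), (16, 1))
    dense_units: int = 32
    learning_rate: float = 0.01
    epochs: int = 10
    batch_size: int = 16
    augment: tuple[str, ...] = AUGMENTATIONS
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.input_size % (2 ** len(self.blocks)) != 0:
            raise ValueError("input size must be divisible by 2^n_blocks")
        unknown = set(self.augment) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")

    @classmethod
    def vgg16(cls, **overrides) -> "CNNConfig":
        """The full five-block, thirteen-convolution topology."""
        base = cls(
            input_size=224,
            channels=3,
            blocks=((64, 2), (128, 2), (256, 3), (512, 3), (512, 3)),
            dense_units=4096,
        )
        from dataclasses import replace
        return replace(base, **overrides)


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patches: (N, C, H, W) -> (N, C, H, W, 9)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.ascontiguousarray(cols).reshape(*x.shape, 9)


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 9))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.cols = _im2col(x)
        return np.einsum("nchwk,ock->nohw", self.cols, self.w) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        dw = np.einsum("nohw,nchwk->ock", dout, self.cols)
        db = dout.sum(axis=(0, 2, 3))
        dcols = np.einsum("nohw,ock->nchwk", dout, self.w)
        N, C, H, W, _ = self.cols.shape
        dxp = np.zeros((N, C, H + 2, W + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + H, j:j + W] += dcols[..., i * 3 + j]
        self.w -= lr * dw
        self.b -= lr * db
        return dxp[:, :, 1:-1, 1:-1]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        return dout * self.mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        win = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(N, C, H // 2, W // 2, 4)
        self.argmax = win.argmax(axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(win, self.argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        N, C, H, W = self.in_shape
        dwin = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(dwin, self.argmax[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dwin.reshape(N, C, H, W)


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        return dout.reshape(self.in_shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None,
                 zero_init: bool = False):
        if zero_init or rng is None:
            self.w = np.zeros((n_in, n_out))
        else:
            self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        dw = self.x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self.w -= lr * dw
        self.b -= lr * db
        return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _augment_one(img: np.ndarray, cfg: CNNConfig, rng: np.random.Generator) -> np.ndarray:
    """Random affine warp of one (C, H, W) image, reflect-padded."""
    H, W = img.shape[1:]
    m = np.eye(2)
    if "rotation" in cfg.augment:
        theta = np.deg2rad(rng.uniform(-15.0, 15.0))
        m = m @ np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
    if "shear" in cfg.augment:
        m = m @ np.array([[1.0, rng.uniform(-0.1, 0.1)], [0.0, 1.0]])
    if "zoom" in cfg.augment:
        m = m * rng.uniform(0.9, 1.1)
    shift = np.zeros(2)
    if "translation" in cfg.augment:
        shift = rng.uniform(-3.0, 3.0, size=2)
    centre = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    offset = centre - m @ centre + shift
    out = np.stack([
        ndimage.affine_transform(ch, m, offset=offset, order=1, mode="reflect")
        for ch in img
    ])
    if "hflip" in cfg.augment and rng.random() < 0.5:
        out = out[:, :, ::-1].copy()
    return out


class CNNClassifier:
    """Fitted convolutional classifier with a scikit-learn-like surface."""

    def __init__(self, cfg: CNNConfig, seed: int = 0):
        if cfg.pretrained:
            raise ValueError(
                "no pretrained weights are bundled; train from random "
                "initialization (pretrained=False)")
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        layers: list = []
        c_in = cfg.channels
        size = cfg.input_size
        for filters, n_convs in cfg.blocks:
            for _ in range(n_convs):
                layers.append(_Conv(c_in, filters, self.rng))
                layers.append(_ReLU())
                c_in = filters
            layers.append(_MaxPool2())
            size //= 2
        layers.append(_Flatten())
        layers.append(_Dense(c_in * size * size, cfg.dense_units, self.rng))
        layers.append(_ReLU())
        self.head = _Dense(cfg.dense_units, 2, None, zero_init=True)
        layers.append(self.head)
        self.layers = layers

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    @staticmethod
    def _to_nchw(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        elif x.ndim == 4 and x.shape[-1] in (1, 3):
            x = x.transpose(0, 3, 1, 2)
        return x / 255.0 if x.max() > 1.5 else x

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        """Pixel z-scoring with training-set statistics."""
        x = self._to_nchw(images)
        if not hasattr(self, "_norm"):
            self._norm = (x.mean(), max(x.std(), 1e-8))
        return (x - self._norm[0]) / self._norm[1]

    def fit(self, images: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        x = self._prepare(images)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"images must be {self.cfg.input_size}x{self.cfg.input_size}")
        targets = (y == POSITIVE).astype(int)
        # prior-matching head bias: the untrained net predicts the priors
        priors = np.bincount(targets, minlength=2) / len(targets)
        self.head.b = np.log(np.maximum(priors, 1e-12))
        self.losses_: list[float] = []
        n = len(x)
        for _ in range(self.cfg.epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start:start + self.cfg.batch_size]
                xb = x[idx]
                if self.cfg.augment:
                    xb = np.stack([_augment_one(im, self.cfg, self.rng) for im in xb])
                tb = targets[idx]
                logits = self._forward(xb)
                probs = _softmax(logits)
                epoch_loss -= float(np.log(
                    np.maximum(probs[np.arange(len(idx)), tb], 1e-12)).sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), tb] -= 1.0
                dlogits /= len(idx)
                grad = dlogits
                for layer in reversed(self.layers):
                    grad = layer.backward(grad, self.cfg.learning_rate)
            self.losses_.append(epoch_loss / n)
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return _softmax(self._forward(self._prepare(images)))

    def predict(self, images: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(images)
        return np.where(proba[:, 1] >= proba[:, 0], POSITIVE, NEGATIVE)

    def decision_function(self, images: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(images)
        return proba[:, 1] - proba[:, 0]


def fit_cnn(images: np.ndarray, y: np.ndarray,
            cfg: CNNConfig = CNNConfig(), seed: int = 0) -> CNNClassifier:
    """Train a CNN on labeled thermogram images (labels in {-1, +1})."""
    return CNNClassifier(cfg, seed=seed).fit(images, y)
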