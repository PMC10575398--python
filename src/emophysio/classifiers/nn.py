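"""Arousal-strength classifier: a small CNN trained with SGD-momentum and
class-weighted cross-entropy.

The default backbone is a compact 4-conv-block network implemented in plain
numpy so training runs on CPU in seconds; a ``resnet50`` backbone can be
requested and is loaded through torch when available (optional extra, not
part of the test surface).  Training follows the stated options: SGD with
momentum, mini-batch 30, learning rate 0.001, 12 epochs, shuffling every
epoch, per-parameter gradient-norm clipping at 1.0, and loss weights
w_i = N / m_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .loss import weighted_cross_entropy

AROUSAL_LABELS = ("low", "mid", "high")


@dataclass(frozen=True)
class CnnTrainConfig:
    backbone: str = "small_cnn"  # {small_cnn, resnet50}
    epochs: int = 12
    mini_batch: int = 30
    learning_rate: float = 0.001
    momentum: float = 0.9
    gradient_threshold: float = 1.0
    input_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.mini_batch < 1:
            raise ValueError("epochs and mini_batch must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class _Conv3x3:
    """Same-padding 3x3 convolution via sliding windows."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, wdt = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
        self._cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wdt, -1)
        self._shape = (n, c, h, wdt)
        out = self._cols @ self.w.T + self.b
        return out.reshape(n, h, wdt, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, wdt = self._shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * wdt, -1)
        self.dw = dmat.T @ self._cols
        self.db = dmat.sum(axis=0)
        dcols = (dmat @ self.w).reshape(n, h, wdt, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, wdt + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + wdt] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("w", self.w, self.vw), ("b", self.b, self.vb)]

    def grads(self):
        return {"w": self.dw, "b": self.db}


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._argmask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = self._argmask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.w

    def params(self):
        return [("w", self.w, self.vw), ("b", self.b, self.vb)]

    def grads(self):
        return {"w": self.dw, "b": self.db}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCnn:
    """4 conv blocks (conv3x3 + ReLU + maxpool2) and a linear head."""

    def __init__(self, input_size: int, n_classes: int, rng: np.random.Generator):
        widths = (8, 16, 32, 32)
        self.blocks = []
        c_in = 3
        for c_out in widths:
            self.blocks.append((_Conv3x3(c_in, c_out, rng), _ReLU(), _MaxPool2()))
            c_in = c_out
        side = input_size // 16
        if side < 1:
            raise ValueError("input_size must be at least 16")
        self.head = _Dense(c_in * side * side, n_classes, rng)
        self.input_size = input_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        for conv, relu, pool in self.blocks:
            x = pool.forward(relu.forward(conv.forward(x)))
        self._feat_shape = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits).reshape(self._feat_shape)
        for conv, relu, pool in reversed(self.blocks):
            d = conv.backward(relu.backward(pool.backward(d)))

    def layers_with_params(self):
        return [conv for conv, _, _ in self.blocks] + [self.head]


@dataclass
class ArousalClassifier:
    net: SmallCnn
    classes: tuple[str, ...]
    config: CnnTrainConfig
    class_weights: np.ndarray
    image_shape: tuple[int, int] = (0, 0)
    history: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _prepare_images(images, self.net.input_size)
        return _softmax(self.net.forward(x))


def _prepare_images(images: np.ndarray, input_size: int) -> np.ndarray:
    """HxWx3 (or stacks thereof) -> N x 3 x S x S in [0, 1]."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected images shaped (N, H, W, 3)")
    if arr.shape[1] != input_size or arr.shape[2] != input_size:
        arr = np.stack(
            [resize(im, (input_size, input_size), order=1, mode="edge", anti_aliasing=False) for im in arr]
        )
    return arr.transpose(0, 3, 1, 2)


def _clip_gradient(g: np.ndarray, threshold: float) -> np.ndarray:
    norm = np.linalg.norm(g)
    if norm > threshold:
        return g * (threshold / norm)
    return g


def class_weight_vector(labels: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    n = labels.size
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    if np.any(counts == 0):
        missing = [c for c, m in zip(classes, counts) if m == 0]
        raise ValueError(f"missing class(es) {missing}: loss weights undefined")
    return n / counts


def train_arousal_classifier(
    images: Sequence[np.ndarray] | np.ndarray,
    labels: Sequence[str],
    cfg: CnnTrainConfig = CnnTrainConfig(),
) -> ArousalClassifier:
    """Train the 3-class (low/mid/high) arousal CNN.

    Loss weights are w_i = N / m_i from the training-label counts; every
    class must be present.  Returns the trained model with per-epoch loss
    and accuracy history.
    """
    if cfg.backbone == "resnet50":
        raise NotImplementedError(
            "resnet50 backbone requires torch + torchvision pretrained weights; "
            "use backbone='small_cnn'"
        )
    if cfg.backbone != "small_cnn":
        raise ValueError(f"unknown backbone {cfg.backbone!r}")
    y = np.asarray(labels)
    classes = AROUSAL_LABELS
    if set(y) - set(AROUSAL_LABELS):
        raise ValueError(f"labels must be in {AROUSAL_LABELS}")
    weights = class_weight_vector(y, classes)
    rng = np.random.default_rng(cfg.seed)
    stack = np.stack(list(images)) if not isinstance(images, np.ndarray) else images
    image_shape = tuple(stack.shape[1:3]) if stack.ndim == 4 else tuple(stack.shape[:2])
    x = _prepare_images(stack, cfg.input_size)
    n = x.shape[0]
    y_idx = np.array([classes.index(c) for c in y])
    onehot = np.eye(len(classes))[y_idx]
    net = SmallCnn(cfg.input_size, len(classes), rng)
    layers = net.layers_with_params()
    loss_hist, acc_hist = [], []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.mini_batch):
            idx = order[start : start + cfg.mini_batch]
            logits = net.forward(x[idx])
            probs = _softmax(logits)
            batch_loss = weighted_cross_entropy(probs, onehot[idx], weights)
            w_row = weights[y_idx[idx]][:, None]
            dlogits = w_row * (probs - onehot[idx]) / idx.size
            net.backward(dlogits)
            for layer in layers:
                grads = layer.grads()
                for name, param, vel in layer.params():
                    g = _clip_gradient(grads[name], cfg.gradient_threshold)
                    vel *= cfg.momentum
                    vel -= cfg.learning_rate * g
                    param += vel
            epoch_losses.append(batch_loss)
        logits = net.forward(x)
        acc = float(np.mean(np.argmax(logits, axis=1) == y_idx))
        loss_hist.append(float(np.mean(epoch_losses)))
        acc_hist.append(acc)
    return ArousalClassifier(
        net=net,
        classes=classes,
        config=cfg,
        class_weights=weights,
        image_shape=image_shape,
        history={"loss": loss_hist, "train_accuracy": acc_hist},
    )


def predict_arousal(model: ArousalClassifier, image: np.ndarray) -> tuple[str, np.ndarray]:
    """Predicted class and the 3-class probability vector for one image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a single HxWx3 image")
    if tuple(img.shape[:2]) != model.image_shape:
        raise ValueError(
            f"image size {img.shape[:2]} does not match training size {model.image_shape}"
        )
    probs = model.predict_proba(img[None])[0]
    return model.classes[int(np.argmax(probs))], probs
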