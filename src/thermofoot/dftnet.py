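"""DFTNet: a small convolutional network for thermogram-patch grading.

The architecture is a fixed nine-layer stack:

====== ========= ======== ====== ===========
Layer  Type      Kernel   Stride Filters
====== ========= ======== ====== ===========
1      Conv      7 x 7    1 x 1  32
2      Max-Pool  3 x 3    2 x 2  --
3      Conv      1 x 1    1 x 1  64
4      Conv      3 x 3    1 x 1  64
5      Max-Pool  3 x 3    2 x 2  --
6      Conv      3 x 3    1 x 1  32
7      Max-Pool  2 x 2    2 x 2  --
8      Conv      3 x 3    1 x 1  32
9      Full Conn --       --     n_classes
====== ========= ======== ====== ===========

Every convolution is same-padded, stride 1, and followed by ReLU; pools
are valid-padded, so a 64x64 input flows 64 -> 31 -> 15 -> 7 through the
three pools.  A softmax follows the fully connected layer, and training
minimizes categorical cross-entropy with Adam (defaults: learning rate
0.001, minibatch 64, at most 100 epochs).

The network is implemented directly on NumPy (im2col convolutions,
max-pool argmax scatter, full backpropagation) with seeded He-uniform
initialization; the output layer starts at near-zero scale so the initial
prediction is uniform and the starting loss is ln(n_classes).  Everything
runs in float32 on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .thermogram import ValidationError

__all__ = ["DFTNetSpec", "TrainConfig", "EarlyStop", "DFTNet", "build", "train", "predict"]


class ShapeError(ValueError):
    """Input too small for the pooling cascade."""


# ---------------------------------------------------------------- layers

class _Conv:
    """Same-padded stride-1 convolution via im2col."""

    def __init__(self, kh: int, kw: int, cin: int, cout: int,
                 rng: np.random.Generator, scale: float = 1.0) -> None:
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        limit = scale * np.sqrt(6.0 / (kh * kw * cin))
        self.W = rng.uniform(-limit, limit, size=(kh * kw * cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._cols: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def out_shape(self, h: int, w: int, c: int) -> Tuple[int, int, int]:
        if c != self.cin:
            raise ShapeError(f"expected {self.cin} channels, got {c}")
        return h, w, self.cout

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        xp = np.pad(x, ((0, 0), (ph, self.kh - 1 - ph), (pw, self.kw - 1 - pw), (0, 0)))
        cols = np.empty((n, h, w, self.kh, self.kw, self.cin), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, :, i, j, :] = xp[:, i:i + h, j:j + w, :]
        flat = cols.reshape(n * h * w, -1)
        out = flat @ self.W + self.b
        if train:
            self._cols, self._xshape = flat, x.shape
        return out.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dyf = dy.reshape(-1, self.cout)
        self.dW = self._cols.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(n, h, w, self.kh, self.kw, self.cin)
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        dxp = np.zeros((n, h + self.kh - 1, w + self.kw - 1, c), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, ph:ph + h, pw:pw + w, :]

    @property
    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _ReLU:
    def out_shape(self, h, w, c):
        return h, w, c

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    params: list = []


class _MaxPool:
    """Valid-padded max pooling, possibly overlapping windows."""

    def __init__(self, k: int, s: int) -> None:
        self.k, self.s = k, s

    def out_shape(self, h: int, w: int, c: int) -> Tuple[int, int, int]:
        ho, wo = (h - self.k) // self.s + 1, (w - self.k) // self.s + 1
        if ho < 1 or wo < 1:
            raise ShapeError(f"{h}x{w} input too small for {self.k}x{self.k} pool")
        return ho, wo, c

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo, _ = self.out_shape(h, w, c)
        win = np.empty((n, ho, wo, c, self.k * self.k), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                win[..., i * self.k + j] = x[:, i:i + self.s * ho:self.s,
                                             j:j + self.s * wo:self.s, :]
        out = win.max(axis=-1)
        if train:
            self._arg = win.argmax(axis=-1)
            self._xshape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        ho, wo = dy.shape[1], dy.shape[2]
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                sel = self._arg == i * self.k + j
                dx[:, i:i + self.s * ho:self.s, j:j + self.s * wo:self.s, :] += dy * sel
        return dx

    params: list = []


class _Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 scale: float = 1.0) -> None:
        limit = scale * np.sqrt(6.0 / din)
        self.W = rng.uniform(-limit, limit, size=(din, dout)).astype(np.float32)
        self.b = np.zeros(dout, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        if train:
            self._x = flat
            self._xshape = x.shape
        return flat @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return (dy @ self.W.T).reshape(self._xshape)

    @property
    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _Adam:
    def __init__(self, layers, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.entries = [(layer, pname, gname) for layer in layers
                        for (param, gname) in layer.params
                        for pname in (["W"] if gname == "dW" else ["b"])]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, p)) for l, p, _ in self.entries]
        self.v = [np.zeros_like(getattr(l, p)) for l, p, _ in self.entries]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for idx, (layer, pname, gname) in enumerate(self.entries):
            g = getattr(layer, gname)
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * g
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * g * g
            mhat = self.m[idx] / (1 - self.b1 ** self.t)
            vhat = self.v[idx] / (1 - self.b2 ** self.t)
            getattr(layer, pname)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ------------------------------------------------------------- the model

#: Table rows of the fixed architecture: (type, kernel, stride, filters)
ARCH_TABLE: Tuple[Tuple[str, Optional[int], Optional[int], Optional[int]], ...] = (
    ("conv", 7, 1, 32),
    ("maxpool", 3, 2, None),
    ("conv", 1, 1, 64),
    ("conv", 3, 1, 64),
    ("maxpool", 3, 2, None),
    ("conv", 3, 1, 32),
    ("maxpool", 2, 2, None),
    ("conv", 3, 1, 32),
    ("fc", None, None, None),
)


@dataclass(frozen=True)
class DFTNetSpec:
    """Architecture parameters; the layer stack itself is immutable."""

    input_shape: Tuple[int, int, int] = (64, 64, 3)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if len(self.input_shape) != 3:
            raise ValidationError("input_shape must be (H, W, C)")

    @property
    def layers(self):
        return ARCH_TABLE


@dataclass(frozen=True)
class EarlyStop:
    """Stop training once a monitored quantity crosses a threshold."""

    monitor: str = "train_accuracy"
    threshold: float = 0.999

    def reached(self, history: Dict[str, List[float]]) -> bool:
        value = history[self.monitor][-1]
        if self.monitor.endswith("loss"):
            return value <= self.threshold
        return value >= self.threshold


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    batch_size: int = 64
    optimizer: str = "adam"
    learning_rate: float = 0.001
    seed: int = 0
    early_stop: Optional[EarlyStop] = None

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")


class DFTNet:
    """Built network: layer objects plus the shape/structure contract."""

    def __init__(self, spec: DFTNetSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w, c = spec.input_shape
        self.layers: List = []
        self._shapes = [(h, w, c)]
        for row_no, (kind, k, s, f) in enumerate(ARCH_TABLE, start=1):
            if kind == "conv":
                layer = _Conv(k, k, c, f, rng)
                self.layers += [layer, _ReLU()]
                h, w, c = layer.out_shape(h, w, c)
            elif kind == "maxpool":
                layer = _MaxPool(k, s)
                try:
                    h, w, c = layer.out_shape(h, w, c)
                except ShapeError as exc:
                    raise ShapeError(f"layer {row_no} (Max-Pool {k}x{k}): {exc}") from exc
                self.layers.append(layer)
            else:  # fully connected
                layer = _Dense(h * w * c, spec.n_classes, rng, scale=0.01)
                self.layers.append(layer)
            self._shapes.append((h, w, c))

    # -- structural contract -------------------------------------------
    def structure(self) -> List[Dict]:
        """Row-per-layer dump mirroring the architecture table."""
        rows = []
        for kind, k, s, f in ARCH_TABLE:
            rows.append({
                "type": {"conv": "Conv.", "maxpool": "Max-Pool", "fc": "Full Conn."}[kind],
                "kernel": None if k is None else (k, k),
                "stride": None if s is None else (s, s),
                "filters": f if kind == "conv" else
                           (self.spec.n_classes if kind == "fc" else None),
            })
        return rows

    def param_count(self) -> int:
        return int(sum(getattr(layer, a).size for layer in self.layers
                       for a in ("W", "b") if hasattr(layer, a)))

    # -- forward / backward --------------------------------------------
    def _logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        if out.ndim == 3:
            out = out[None]
        if out.shape[1:] != tuple(self.spec.input_shape):
            raise ShapeError(
                f"input shape {out.shape[1:]} != expected {self.spec.input_shape}")
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax over the fully connected output)."""
        return _softmax(self._logits(x, train=False))

    def _backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build(spec: DFTNetSpec, seed: int = 0) -> DFTNet:
    """Construct the network with seeded He-uniform initial weights."""
    return DFTNet(spec, seed=seed)


def train(
    model: DFTNet,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> Dict[str, List[float]]:
    """Minimize cross-entropy with Adam; returns the per-epoch history.

    ``X`` is (N, H, W, C) matching the spec's input shape; ``y`` holds
    1-based class labels in [1, n_classes].  The loss trajectory is
    reproducible for a fixed ``cfg.seed``.  History keys:
    ``train_loss`` and ``train_accuracy`` (epoch means over minibatches).
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y).astype(int)
    if len(X) == 0:
        raise ValidationError("empty dataset")
    if len(X) != len(y):
        raise ValidationError("X and y differ in length")
    nc = model.spec.n_classes
    if y.min() < 1 or y.max() > nc:
        raise ValidationError(f"labels must lie in [1, {nc}]")
    if len(np.unique(y)) < 2:
        raise ValidationError("training needs at least two classes present")

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.layers, lr=cfg.learning_rate)
    onehot = np.eye(nc, dtype=np.float32)[y - 1]
    history: Dict[str, List[float]] = {"train_loss": [], "train_accuracy": []}

    for _ in range(cfg.max_epochs):
        perm = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            logits = model._logits(X[idx], train=True)
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(float(-np.mean(
                np.sum(onehot[idx] * np.log(probs + eps), axis=1))) * len(idx))
            correct += int((probs.argmax(axis=1) + 1 == y[idx]).sum())
            dlogits = (probs - onehot[idx]) / len(idx)
            model._backward(dlogits)
            opt.step()
        history["train_loss"].append(sum(losses) / len(X))
        history["train_accuracy"].append(correct / len(X))
        if cfg.early_stop is not None and cfg.early_stop.reached(history):
            break
    return history


def predict(model: DFTNet, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Class probabilities and 1-based argmax labels (lowest-index ties)."""
    probs = model.forward(X)
    return probs, probs.argmax(axis=1) + 1
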