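"""Minimal numpy CNN engine for the scratch backbone.

Implements exactly what the classifier needs on CPU: 3x3 same-padding
convolutions (im2col), ReLU, 2x2 max pooling, dense layers, inverted
dropout, softmax cross-entropy and Adam.  All randomness flows through
explicit ``numpy.random.Generator`` objects, so training is reproducible
for a fixed seed and thread count.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix with zero same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (N,C,H,W,k,k) -> (N,H,W,C,k,k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: tuple, k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = shape
    p = k // 2
    out = np.zeros((n, c, h + 2 * p, w + 2 * p))
    cols = cols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + h, j:j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return out[:, :, p:p + h, p:p + w]


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in * 9, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        self._cols = _im2col(x)
        out = self._cols @ self.w + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, co, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, co)
        self.dw = self._cols.T @ g
        self.db = g.sum(axis=0)
        return _col2im(g @ self.w.T, self._shape)


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2:
    """2x2 stride-2 max pooling; odd trailing rows/cols are dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xv = x[:, :, :2 * oh, :2 * ow].reshape(n, c, oh, 2, ow, 2)
        out = xv.max(axis=(3, 5))
        mask = xv == out[:, :, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        return out

    def backward(self, grad):
        n, c, h, w = self._in_shape
        oh, ow = h // 2, w // 2
        g = self._mask * grad[:, :, :, None, :, None]
        out = np.zeros(self._in_shape)
        out[:, :, :2 * oh, :2 * ow] = g.reshape(n, c, 2 * oh, 2 * ow)
        return out


class Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T


class Dropout:
    """Inverted dropout; active only when a train-mode rng is supplied."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, rng: np.random.Generator | None = None):
        if rng is None or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params_and_grads) -> None:
        self.t += 1
        for key, (p, g) in enumerate(params_and_grads):
            m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[key] = (m, v)
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class ScratchCNN:
    """3 conv blocks (conv-ReLU-pool) + FC head (ReLU, dropout, softmax).

    The conv blocks form the "backbone"; the two dense layers form the
    trainable head.  When ``freeze_backbone`` the conv parameters receive no
    updates (useful to mimic feature-extraction-only transfer learning).
    """

    def __init__(self, input_side: int, hidden: int = 256,
                 dropout_rate: float = 0.6, conv_channels=(8, 16, 32),
                 n_classes: int = 2, seed: int = 0,
                 freeze_backbone: bool = False):
        rng = np.random.default_rng(seed)
        self.input_side = input_side
        self.freeze_backbone = freeze_backbone
        side = input_side
        chans = [1, *conv_channels]
        self.convs, self.pools, self.relus = [], [], []
        for c_in, c_out in zip(chans[:-1], chans[1:]):
            self.convs.append(Conv3x3(c_in, c_out, rng))
            self.relus.append(ReLU())
            self.pools.append(MaxPool2())
            side //= 2
        self.flat = Flatten()
        self.fc1 = Dense(chans[-1] * side * side, hidden, rng)
        self.fc_relu = ReLU()
        self.drop = Dropout(dropout_rate)
        self.fc2 = Dense(hidden, n_classes, rng)

    # --- parameter access -------------------------------------------------
    def _layers_with_params(self):
        return [("backbone", c) for c in self.convs] + \
               [("head", self.fc1), ("head", self.fc2)]

    def parameters(self, trainable_only: bool = False):
        out = []
        for group, layer in self._layers_with_params():
            if trainable_only and self.freeze_backbone and group == "backbone":
                continue
            out.append(layer.w)
            out.append(layer.b)
        return out

    def gradients(self, trainable_only: bool = False):
        out = []
        for group, layer in self._layers_with_params():
            if trainable_only and self.freeze_backbone and group == "backbone":
                continue
            out.append(layer.dw)
            out.append(layer.db)
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    def backbone_checksum(self) -> float:
        return float(sum(np.abs(c.w).sum() + np.abs(c.b).sum()
                         for c in self.convs))

    # --- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """x: (N, side, side) grayscale; rng enables dropout (training mode)."""
        h = np.asarray(x, dtype=float)[:, None, :, :]
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        h = self.fc_relu.forward(self.fc1.forward(self.flat.forward(h)))
        h = self.drop.forward(h, rng)
        return self.fc2.forward(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, rng=None))

    def backward(self, probs: np.ndarray, y: np.ndarray) -> None:
        n = len(y)
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        grad = self.fc2.backward(grad)
        grad = self.drop.backward(grad)
        grad = self.flat.backward(self.fc1.backward(self.fc_relu.backward(grad)))
        for conv, relu, pool in zip(reversed(self.convs), reversed(self.relus),
                                    reversed(self.pools)):
            grad = conv.backward(relu.backward(pool.backward(grad)))

    def train_step(self, x, y, optimizer: Adam,
                   rng: np.random.Generator) -> tuple[float, float]:
        """One minibatch update; returns (loss, accuracy) before the update."""
        probs = softmax(self.forward(x, rng=rng))
        loss = cross_entropy(probs, y)
        acc = float((probs.argmax(axis=1) == y).mean())
        self.backward(probs, y)
        optimizer.step(zip(self.parameters(trainable_only=True),
                           self.gradients(trainable_only=True)))
        return loss, acc
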