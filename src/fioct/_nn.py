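"""Minimal CPU conv-net engine (numpy) used by the B-scan classifier.

Implements exactly the blocks the classifier needs — 2D convolution
(same-padding, stride 1, im2col + GEMM), 2x2 max-pooling, ReLU, flatten,
dense, inverted dropout — with softmax / categorical cross-entropy loss and
an Adam optimizer.  Everything is float32 and seeded through a single
``numpy.random.Generator``, so training is reproducible on one platform
with a fixed BLAS.

Gradients are exact (no autograd); the test suite verifies them against
finite differences on small inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SequentialCNN", "softmax", "cross_entropy"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix, same-padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H*W, C*k*k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + h, pad:pad + w]


class _Layer:
    def forward(self, x, train, rng):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def params(self):
        return []  # list of [param, grad] pairs


class Conv2D(_Layer):
    """3x3 (configurable) same-padding convolution, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = rng.normal(0.0, scale, size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k, self.pad = k, k // 2
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k, self.pad)
        n, c, h, w = x.shape
        out = self.cols @ self.w.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, oc, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n, h * w, oc)
        self.dw[...] = np.einsum("npo,npf->of", g, self.cols, optimize=True)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.w
        return _col2im(dcols, self.x_shape, self.k, self.pad)

    def params(self):
        return [[self.w, self.dw], [self.b, self.db]]


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class MaxPool2(_Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        self.xr_shape = xr.shape
        flat = xr.reshape(n, c, h2, w2, 4)
        self.idx = flat.argmax(axis=4)
        self.in_shape = x.shape
        return np.take_along_axis(flat, self.idx[..., None], axis=4)[..., 0]

    def backward(self, grad):
        n, c, h2, w2 = grad.shape
        dflat = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(dflat, self.idx[..., None], grad[..., None], axis=4)
        dxr = dflat.reshape(self.xr_shape).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(self.in_shape)


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.in_shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self.x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [[self.w, self.dw], [self.b, self.db]]


class Dropout(_Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy."""
    return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))


class _Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params) -> None:
        self.t += 1
        for pid, (p, g) in enumerate(params):
            if pid not in self.state:
                self.state[pid] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[pid]
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SequentialCNN:
    """conv/pool blocks -> flatten -> dense -> dropout -> dense softmax."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        n_classes: int = 2,
        conv_channels: tuple[int, ...] = (8, 16, 32),
        kernel_size: int = 3,
        dense_units: int = 64,
        dropout: float = 0.5,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.rng = np.random.default_rng(seed)
        h, w = input_shape
        layers: list[_Layer] = []
        in_ch = 1
        for ch in conv_channels:
            if h % 2 or w % 2:
                raise ValueError("input size must be divisible by 2 per pool stage")
            layers += [Conv2D(in_ch, ch, kernel_size, self.rng), ReLU(), MaxPool2()]
            in_ch = ch
            h, w = h // 2, w // 2
        layers += [Flatten(), Dense(h * w * in_ch, dense_units, self.rng), ReLU(),
                   Dropout(dropout), Dense(dense_units, n_classes, self.rng)]
        self.layers = layers
        self.n_classes = n_classes
        self.input_shape = input_shape
        self.opt = _Adam(lr=learning_rate)
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    # -- plumbing -----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return out

    def _params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # -- public api ---------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int,
        batch_size: int = 16,
    ) -> dict[str, list[float]]:
        """Train with softmax cross-entropy; records per-epoch loss/accuracy."""
        x = np.asarray(images, dtype=np.float32)[:, None, :, :]
        y = np.asarray(labels, dtype=int)
        onehot = np.eye(self.n_classes, dtype=np.float32)[y]
        n = len(x)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], onehot[idx]
                logits = self._forward(xb, train=True)
                probs = softmax(logits)
                losses.append(cross_entropy(probs, yb) * len(idx))
                correct += int((probs.argmax(1) == y[idx]).sum())
                grad = (probs - yb).astype(np.float32) / len(idx)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self.opt.step(self._params())
            self.history["loss"].append(sum(losses) / n)
            self.history["accuracy"].append(correct / n)
        return self.history

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)[:, None, :, :]
        out = [
            softmax(self._forward(x[i:i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    # -- persistence --------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self._params()]

    def set_weights(self, weights) -> None:
        params = self._params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for (p, _), w in zip(params, weights):
            p[...] = w
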