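"""A small convolutional network for single-channel square images,
implemented directly on numpy.

Architecture: two conv blocks (3x3 kernels, ReLU, 2x2 max-pool) followed by
one dense ReLU layer and a sigmoid output, trained with binary cross-entropy
and Adam, with early stopping on a held-back validation split. No deep
learning framework is available in the runtime, so forward and backward
passes are written out explicitly; a numerical-gradient test guards them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SimpleCNN"]


def _im2col(x: np.ndarray, ksize: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H', W', k, k, C) sliding patches."""
    v = sliding_window_view(x, (ksize, ksize), axis=(1, 2))
    # sliding_window_view yields (N, H', W', C, k, k); put channels last
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))


def _col2im(dcol: np.ndarray, in_shape: tuple) -> np.ndarray:
    """Scatter-add patch gradients back onto the input tensor."""
    n, h, w, c = in_shape
    k = dcol.shape[3]
    ho, wo = dcol.shape[1], dcol.shape[2]
    dx = np.zeros(in_shape)
    for di in range(k):
        for dj in range(k):
            dx[:, di:di + ho, dj:dj + wo, :] += dcol[:, :, :, di, dj, :]
    return dx


class _Conv:
    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        fan_in = ksize * ksize * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (ksize, ksize, c_in, c_out))
        self.b = np.zeros(c_out)
        self.ksize = ksize

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        col = _im2col(x, self.ksize)
        self._col = col
        n, ho, wo = col.shape[:3]
        flat = col.reshape(n * ho * wo, -1)
        out = flat @ self.W.reshape(-1, self.W.shape[-1]) + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, ho, wo, co = dout.shape
        dflat = dout.reshape(n * ho * wo, co)
        flat = self._col.reshape(n * ho * wo, -1)
        self.dW = (flat.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcol = (dflat @ self.W.reshape(-1, co).T).reshape(self._col.shape)
        return _col2im(dcol, self._x_shape)

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list = []
    grads: list = []


class _MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        self._x_shape = x.shape
        xr = x[:, : 2 * ho, : 2 * wo, :]
        xr = xr.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, ho, wo, 4, c)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, ho, wo, c = dout.shape
        dxr = np.zeros((n, ho, wo, 4, c))
        np.put_along_axis(
            dxr, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3
        )
        dxr = dxr.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._x_shape)
        dx[:, : 2 * ho, : 2 * wo, :] = dxr.reshape(n, 2 * ho, 2 * wo, c)
        return dx

    params: list = []
    grads: list = []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    params: list = []
    grads: list = []


@dataclass
class SimpleCNN:
    """Binary image classifier: conv(16)-pool-conv(32)-pool-dense(64)-sigmoid."""

    input_shape: tuple[int, int] = (21, 21)
    conv_channels: tuple[int, int] = (16, 32)
    kernel_size: int = 3
    dense_units: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 32
    max_epochs: int = 100
    min_epochs: int = 30
    patience: int = 10
    val_fraction: float = 0.15
    seed: int = 0
    _layers: list = field(init=False, repr=False, default_factory=list)

    def _build(self) -> None:
        rng = np.random.default_rng(self.seed)
        h, w = self.input_shape
        c1, c2 = self.conv_channels
        k = self.kernel_size
        self._layers = [_Conv(1, c1, k, rng), _ReLU(), _MaxPool2()]
        h, w = (h - k + 1) // 2, (w - k + 1) // 2
        self._layers += [_Conv(c1, c2, k, rng), _ReLU(), _MaxPool2()]
        h, w = (h - k + 1) // 2, (w - k + 1) // 2
        if h < 1 or w < 1:
            raise ValueError(f"input shape {self.input_shape} too small")
        self._layers += [
            _Flatten(),
            _Dense(h * w * c2, self.dense_units, rng),
            _ReLU(),
            _Dense(self.dense_units, 1, rng),
        ]
        self._rng = rng

    def _forward(self, x: np.ndarray) -> np.ndarray:
        out = x[..., None] if x.ndim == 3 else x
        for layer in self._layers:
            out = layer.forward(out)
        return out[:, 0]  # logits

    def _backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits[:, None]
        for layer in reversed(self._layers):
            dout = layer.backward(dout)

    def _param_arrays(self) -> list[np.ndarray]:
        return [p for layer in self._layers for p in layer.params]

    def _grad_arrays(self) -> list[np.ndarray]:
        return [g for layer in self._layers for g in layer.grads]

    def _parameters(self):
        yield from zip(self._param_arrays(), self._grad_arrays())

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean binary cross-entropy; leaves gradients on the layers."""
        logits = self._forward(x)
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        self._backward((p - y) / len(y))
        return float(loss)

    def _eval_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        p = _sigmoid(self._forward(x))
        eps = 1e-12
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "SimpleCNN":
        x = np.asarray(images, dtype=float)
        y = np.asarray(labels, dtype=float)
        self.input_shape = x.shape[1:3]
        self._build()
        rng = self._rng

        n = len(x)
        n_val = int(round(self.val_fraction * n))
        if n_val < 2 or n < 8:
            n_val = 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if n_val and (len(np.unique(y[val_idx])) < 2 or len(np.unique(y[tr_idx])) < 2):
            n_val = 0  # tiny or degenerate split: train on everything
        if n_val:
            x_val, y_val = x[val_idx], y[val_idx]
            x_tr, y_tr = x[tr_idx], y[tr_idx]
        else:
            x_tr, y_tr = x, y

        # Adam state
        pg = self._param_arrays()
        m_state = [np.zeros_like(p) for p in pg]
        v_state = [np.zeros_like(p) for p in pg]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss = np.inf
        best_params = [p.copy() for p in pg]
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(x_tr))
            for start in range(0, len(x_tr), self.batch_size):
                batch = order[start : start + self.batch_size]
                self.loss_and_grads(x_tr[batch], y_tr[batch])
                t += 1
                for i, (p, g) in enumerate(self._parameters()):
                    if self.weight_decay:
                        g = g + self.weight_decay * p
                    m_state[i] = beta1 * m_state[i] + (1 - beta1) * g
                    v_state[i] = beta2 * v_state[i] + (1 - beta2) * g * g
                    mhat = m_state[i] / (1 - beta1**t)
                    vhat = v_state[i] / (1 - beta2**t)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            monitor = (
                self._eval_loss(x_val, y_val)
                if n_val
                else self._eval_loss(x_tr, y_tr)
            )
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_params = [p.copy() for p in pg]
                stall = 0
            else:
                stall += 1
                if epoch + 1 >= self.min_epochs and stall >= self.patience:
                    break
        for p, best in zip(pg, best_params):
            p[...] = best
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        return _sigmoid(self._forward(x))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
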