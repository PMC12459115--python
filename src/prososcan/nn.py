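"""A compact convolutional network implemented on numpy.

Architecture (fixed up to feature-map counts): three blocks of
[3x3 convolution, stride 2, zero padding 1] -> rectifier -> [3x3 max
pool, stride 2, padding 1], with 32, 64 and 128 feature maps, followed by
a flatten and a single sigmoid unit.  Both spatial operators halve each
dimension (ceil), so an H x W input reaches the dense layer at
ceil(H/64) x ceil(W/64) x 128.

Training minimizes (optionally class-weighted) binary cross-entropy with
Adam; the epoch is selected by early stopping on a held-out validation
loss.  Internals use NHWC layout and im2col GEMMs in float32; the
backward pass is gradient-checked against finite differences in the test
suite (in float64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TrainConfig", "ConvNet", "binary_cross_entropy"]

_EPS = 1e-7


def binary_cross_entropy(y: np.ndarray, p: np.ndarray, eps: float = _EPS) -> float:
    """Mean binary cross-entropy with probability clipping.

    -(1/n) * sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _half(n: int) -> int:
    # 3x3 window, stride 2, pad 1 -> ceil(n / 2) output positions
    return (n - 1) // 2 + 1


def _strided_windows(xp: np.ndarray) -> np.ndarray:
    """3x3 windows at stride 2 of a padded (N, H, W, C) array, as a
    contiguous (N, Ho, Wo, C, 9) copy."""
    w = sliding_window_view(xp, (3, 3), axis=(1, 2))[:, ::2, ::2]  # (N,Ho,Wo,C,3,3)
    n, ho, wo, c = w.shape[:4]
    return np.ascontiguousarray(w).reshape(n, ho, wo, c, 9)


class _Conv:
    """3x3 convolution, stride 2, zero padding 1 (NHWC)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_in * 9, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = _strided_windows(xp)  # (N, Ho, Wo, C, 9)
        ho, wo = cols.shape[1], cols.shape[2]
        self._cols = cols.reshape(n * ho * wo, c * 9)
        self._in_shape = x.shape
        self._out_hw = (ho, wo)
        out = self._cols @ self.W + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = self._out_hw
        dflat = dout.reshape(n * ho * wo, -1)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, ho, wo, c, 3, 3)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dout.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + 2 * ho : 2, j : j + 2 * wo : 2, :] += dcols[:, :, :, :, i, j]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]

    def params(self):
        return ["W", "b"]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool:
    """3x3 max pool, stride 2, padding 1 (padding value -inf)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.full((n, h + 2, w + 2, c), -np.inf, dtype=x.dtype)
        xp[:, 1 : 1 + h, 1 : 1 + w, :] = x
        win = _strided_windows(xp)  # (N, Ho, Wo, C, 9)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = dout.shape[1], dout.shape[2]
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dout.dtype)
        for t in range(9):
            i, j = t // 3, t % 3
            contrib = dout * (self._argmax == t)
            dxp[:, i : i + 2 * ho : 2, j : j + 2 * wo : 2, :] += contrib
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class _Dense:
    """Flattened features -> single logit."""

    def __init__(self, d_in: int, rng: np.random.Generator, dtype):
        self.W = rng.normal(0.0, np.sqrt(1.0 / d_in), size=d_in).astype(dtype)
        self.b = np.zeros(1, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.reshape(x.shape[0], -1)
        return self._x @ self.W + self.b[0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dlogit
        self.db = dlogit.sum(keepdims=True)
        return dlogit[:, None] * self.W[None, :]

    def params(self):
        return ["W", "b"]


@dataclass
class TrainConfig:
    """Optimization settings (the architecture itself is fixed)."""

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10
    class_weight: bool = True
    seed: int = 0


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, layers) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            for name in layer.params():
                g = getattr(layer, "d" + name)
                key = (li, name)
                m = self.m.get(key, 0.0) * self.b1 + (1 - self.b1) * g
                v = self.v.get(key, 0.0) * self.b2 + (1 - self.b2) * g**2
                self.m[key], self.v[key] = m, v
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                getattr(layer, name)[...] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    getattr(layer, name).dtype
                )


class ConvNet:
    """Three-block conv-net with a single sigmoid output unit."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        channels: tuple[int, int, int] = (32, 64, 128),
        seed: int = 0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        h, w = int(input_shape[0]), int(input_shape[1])
        self.input_shape = (h, w)
        self.dtype = dtype
        self.layers: list = []
        c_in = 1
        for c_out in channels:
            self.layers += [_Conv(c_in, c_out, rng, dtype), _ReLU(), _MaxPool()]
            h, w = _half(_half(h)), _half(_half(w))
            c_in = c_out
        self.dense = _Dense(h * w * c_in, rng, dtype)

    # -- inference ---------------------------------------------------------

    def _logits(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=self.dtype)
        if out.ndim == 3:
            out = out[:, :, :, None]  # single input channel
        for layer in self.layers:
            out = layer.forward(out)
        self._feat_shape = out.shape
        return self.dense.forward(out)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted probability of the positive (prosopagnosic) class."""
        x = np.asarray(x)
        probs = []
        for start in range(0, len(x), batch_size):
            z = self._logits(x[start : start + batch_size]).astype(np.float64)
            probs.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(probs) if probs else np.empty(0)

    # -- training ----------------------------------------------------------

    def _backprop(self, x: np.ndarray, y: np.ndarray, sample_w: np.ndarray) -> float:
        z = self._logits(x).astype(np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        pc = np.clip(p, _EPS, 1 - _EPS)
        wsum = sample_w.sum()
        loss = float(-(sample_w * (y * np.log(pc) + (1 - y) * np.log(1 - pc))).sum() / wsum)
        dlogit = (sample_w * (p - y) / wsum).astype(self.dtype)
        dflat = self.dense.backward(dlogit)
        dout = dflat.reshape(self._feat_shape)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    @property
    def _param_layers(self):
        return [l for l in self.layers if hasattr(l, "params")] + [self.dense]

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        config: TrainConfig | None = None,
    ) -> dict:
        """Train with Adam + early stopping on validation loss.

        Returns a history dict with per-epoch train/validation losses and
        the selected epoch.  Deterministic for a fixed config seed.
        """
        config = config or TrainConfig()
        x = np.asarray(x)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        rng = np.random.default_rng(config.seed)
        if config.class_weight:
            w1 = len(y) / (2.0 * max(y.sum(), 1.0))
            w0 = len(y) / (2.0 * max((1 - y).sum(), 1.0))
            weights = np.where(y == 1, w1, w0)
        else:
            weights = np.ones_like(y)
        opt = _Adam(config.learning_rate)
        history = {"train_loss": [], "val_loss": [], "best_epoch": 0}
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        for epoch in range(config.epochs):
            order = rng.permutation(len(y))
            epoch_loss = 0.0
            for start in range(0, len(y), config.batch_size):
                idx = order[start : start + config.batch_size]
                loss = self._backprop(x[idx], y[idx], weights[idx])
                opt.step(self._param_layers)
                epoch_loss += loss * len(idx)
            history["train_loss"].append(epoch_loss / len(y))
            if x_val is not None and len(x_val):
                val_loss = binary_cross_entropy(y_val, self.predict(x_val))
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_state = [
                        {n: np.copy(getattr(l, n)) for n in l.params()} for l in self._param_layers
                    ]
                    history["best_epoch"] = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs > config.patience:
                        break
        if best_state is not None:
            for layer, state in zip(self._param_layers, best_state):
                for n, val in state.items():
                    setattr(layer, n, val)
        return history
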