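"""Minimal feed-forward building blocks (float32, explicit backprop).

Implements exactly what the two-branch CCS network needs: valid 1D
convolution via im2col, max/average pooling, dense layers, ReLU, He
initialization and the Adam optimizer.  Arrays are channels-last:
``(batch, length, channels)`` for spatial data.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    """He (ReLU-oriented) normal initialization."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass


class Conv1D(Layer):
    """Valid 1D convolution, stride 1: (B, L, C_in) -> (B, L-k+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, needs_input_grad: bool = True):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.needs_input_grad = needs_input_grad
        self.W = np.zeros((c_out, kernel * c_in), dtype=DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._in_len = 0

    def initialize(self, rng: np.random.Generator) -> None:
        self.W = he_init(rng, self.kernel * self.c_in, self.W.shape)
        self.b = np.zeros(self.c_out, dtype=DTYPE)

    def out_len(self, L: int) -> int:
        return L - self.kernel + 1

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (B, L, C) -> (B, L-k+1, k*C) with window positions contiguous
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (B, L-k+1, C, k) -> (B, L-k+1, k, C)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], -1, self.kernel * self.c_in
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_len = x.shape[1]
        col = self._im2col(x)
        if train:
            self._col = col
        return col @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        col = self._col
        B, Lo, _ = dy.shape
        dy2 = dy.reshape(-1, self.c_out)
        self.dW[...] = dy2.T @ col.reshape(-1, self.kernel * self.c_in)
        self.db[...] = dy2.sum(axis=0)
        self._col = None
        if not self.needs_input_grad:  # first layer: skip the input gradient
            return None
        dcol = dy @ self.W  # (B, Lo, k*C_in)
        dx = np.zeros((B, self._in_len, self.c_in), dtype=DTYPE)
        for t in range(self.kernel):
            dx[:, t : t + Lo, :] += dcol[:, :, t * self.c_in : (t + 1) * self.c_in]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Pool1D(Layer):
    """Subsampling with kernel = stride = 2 (max by default, mean optional)."""

    def __init__(self, kind: str = "max"):
        if kind not in ("max", "avg"):
            raise ValueError("pool kind must be 'max' or 'avg'")
        self.kind = kind
        self._argmax: np.ndarray | None = None
        self._in_len = 0

    @staticmethod
    def out_len(L: int) -> int:
        return L // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_len = x.shape[1]
        Lo = self._in_len // 2
        xv = x[:, : 2 * Lo].reshape(x.shape[0], Lo, 2, x.shape[2])
        if self.kind == "avg":
            return xv.mean(axis=2)
        if train:
            self._argmax = xv.argmax(axis=2)
        return xv.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Lo, C = dy.shape
        dxv = np.zeros((B, Lo, 2, C), dtype=DTYPE)
        if self.kind == "avg":
            dxv[:, :, 0, :] = dy * 0.5
            dxv[:, :, 1, :] = dy * 0.5
        else:
            np.put_along_axis(dxv, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
            self._argmax = None
        dx = np.zeros((B, self._in_len, C), dtype=DTYPE)
        dx[:, : 2 * Lo] = dxv.reshape(B, 2 * Lo, C)
        return dx


class Dense(Layer):
    """Fully connected layer: (B, d_in) -> (B, d_out)."""

    def __init__(self, d_in: int, d_out: int):
        self.d_in, self.d_out = d_in, d_out
        self.W = np.zeros((d_out, d_in), dtype=DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def initialize(self, rng: np.random.Generator) -> None:
        self.W = he_init(rng, self.d_in, self.W.shape)
        self.b = np.zeros(self.d_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 3e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
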