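"""Layer primitives with hand-written backward passes.

All tensors are ``float32`` and use the NCHW layout.  Convolutions are
stride-1, zero-padded 'same' convolutions realised as im2col + matmul; the
input gradient is computed as a full convolution with the spatially flipped,
channel-transposed kernel, so both directions run through BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AdaptiveAvgPool2d",
    "Flatten",
    "Linear",
    "Sequential",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) zero-padded -> (N*H*W, C*k*k) patch matrix."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (N, C, H, W, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Layer:
    """Base class: stateless unless it declares parameters."""

    train_mode: bool = True

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def set_mode(self, train: bool) -> None:
        self.train_mode = train


class Conv2d(Layer):
    """3x3 (or kxk, odd k) stride-1 'same' convolution with bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel_size
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel_size * kernel_size
        # He initialisation, suited to the ReLU nonlinearity that follows
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] = ()

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        n, c, h, w = x.shape
        self._shape = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if self.train_mode else None
        out = cols @ self.W.T + self.b
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, h, w = self._shape
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        d2 = np.ascontiguousarray(d2, dtype=np.float32)
        self.dW[...] = d2.T @ self._cols
        self.db[...] = d2.sum(axis=0)
        # input gradient = full conv of dout with flipped kernels
        k = self.k
        Wk = self.W.reshape(self.out_ch, self.in_ch, k, k)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.in_ch, self.out_ch * k * k)
        dcols = _im2col(dout, k)
        dx = (dcols @ Wflip.T).reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with running statistics.

    ``collecting`` mode accumulates equally weighted batch statistics; it is
    used to rebuild the running mean/variance after weight averaging, when the
    stored statistics no longer describe the installed weights.
    """

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.collecting = False
        self._collect_n = 0
        self._cache: tuple | None = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def start_stat_collection(self):
        self.collecting = True
        self._collect_n = 0
        self.running_mean[...] = 0.0
        self.running_var[...] = 0.0

    def finish_stat_collection(self):
        if self._collect_n == 0:
            raise RuntimeError("no batches seen during statistic collection")
        self.running_mean /= self._collect_n
        self.running_var /= self._collect_n
        self.collecting = False

    def forward(self, x):
        if self.train_mode or self.collecting:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.collecting:
                self.running_mean += mean
                self.running_var += var
                self._collect_n += 1
            else:
                m = self.momentum
                self.running_mean[...] = (1 - m) * self.running_mean + m * mean
                self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        xhat = xhat.astype(np.float32)
        if self.train_mode:
            self._cache = (xhat, invstd.astype(np.float32))
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, invstd = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        s1 = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (g * invstd[None, :, None, None] / n) * (n * dout - s1 - xhat * s2)
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x):
        out = np.maximum(x, 0.0)
        if self.train_mode:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2x2/stride-2 max pooling; odd trailing rows/columns are dropped."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x):
        n, c, h, w = x.shape
        hb, wb = h // 2, w // 2
        xc = x[:, :, : hb * 2, : wb * 2]
        blocks = xc.reshape(n, c, hb, 2, wb, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, hb, wb, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if self.train_mode:
            self._cache = (x.shape, idx)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        (n, c, h, w), idx = self._cache
        hb, wb = h // 2, w // 2
        dblocks = np.zeros((n, c, hb, wb, 4), dtype=np.float32)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : hb * 2, : wb * 2] = (
            dblocks.reshape(n, c, hb, wb, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hb * 2, wb * 2)
        )
        self._cache = None
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling onto a fixed output grid, whatever the input size.

    Bin b on an axis of length L covers [floor(b*L/G), ceil((b+1)*L/G)).
    """

    def __init__(self, grid: tuple[int, int] = (1, 1)):
        self.grid = grid
        self._cache: tuple | None = None

    @staticmethod
    def _bins(length: int, g: int) -> list[tuple[int, int]]:
        return [(int(np.floor(b * length / g)), int(np.ceil((b + 1) * length / g)))
                for b in range(g)]

    def forward(self, x):
        n, c, h, w = x.shape
        gh, gw = self.grid
        hb, wb = self._bins(h, gh), self._bins(w, gw)
        out = np.empty((n, c, gh, gw), dtype=np.float32)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                out[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        if self.train_mode:
            self._cache = ((n, c, h, w), hb, wb)
        return out

    def backward(self, dout):
        (n, c, h, w), hb, wb = self._cache
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += dout[:, :, i, j][:, :, None, None] / area
        self._cache = None
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple[int, ...] = ()

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_f, self.out_f = in_f, out_f
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_f),
                            size=(out_f, in_f)).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x: np.ndarray | None = None

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.dW}
        if self.b is not None:
            g["b"] = self.db
        return g

    def forward(self, x):
        if self.train_mode:
            self._x = x
        out = x @ self.W.T
        if self.b is not None:
            out = out + self.b
        return out

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        if self.b is not None:
            self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def set_mode(self, train: bool) -> None:
        self.train_mode = train
        for lyr in self.layers:
            lyr.set_mode(train)

    def forward(self, x):
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dout):
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return dout

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lyr in enumerate(self.layers):
            for name, arr in lyr.params().items():
                out[f"{i}.{type(lyr).__name__}.{name}"] = arr
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, lyr in enumerate(self.layers):
            for name, arr in lyr.grads().items():
                out[f"{i}.{type(lyr).__name__}.{name}"] = arr
        return out
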