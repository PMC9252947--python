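"""Minimal convolutional network kernels with explicit backpropagation.

A small, self-contained NumPy implementation of the layers needed by the
2-D U-Net regressor: 3x3/1x1 convolutions (im2col + GEMM), ReLU, 2x2 max
pooling, nearest-neighbour upsampling, channel concatenation, inverted
dropout, and an Adam optimizer.  Arrays are channel-last,
``(N, H, W, C)``; float32 is used for training and float64 is supported
for finite-difference gradient checking.

The scope is deliberately narrow: stride-1 same-padding convolutions and
factor-2 pooling/upsampling, which is all the U-Net here uses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "Dropout", "Adam"]


def im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (N,H,W,C) -> (N*H*W, 9*C)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, h, w, 3, 3, c), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return np.ascontiguousarray(view).reshape(n * h * w, 9 * c)


class Conv2d:
    """Stride-1 convolution with same padding (kernel 3 or 1) plus bias.

    Weights are stored GEMM-ready as ``(k*k*c_in, c_out)``.  The backward
    data pass is computed as a convolution of the upstream gradient with
    the spatially flipped, channel-transposed kernel, so both directions
    run through the same im2col + GEMM path.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
        weight_scale: float | None = None,
        dtype=np.float32,
    ):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.W = (rng.standard_normal((fan_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [(self, "W"), (self, "b")]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._shape = x.shape
        if self.kernel == 1:
            self._col = x.reshape(-1, self.c_in)
        else:
            self._col = im2col3(x)
        y = self._col @ self.W + self.b
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape  # type: ignore[misc]
        dyf = dy.reshape(-1, self.c_out)
        self.dW = self._col.T @ dyf  # type: ignore[union-attr]
        self.db = dyf.sum(axis=0)
        if self.kernel == 1:
            return (dyf @ self.W.T).reshape(self._shape)
        # full correlation with flipped kernel: dX = conv(dY, flip(W)^T)
        wk = self.W.reshape(3, 3, self.c_in, self.c_out)
        w_back = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.c_out, self.c_in)
        dx = im2col3(dy) @ w_back
        return dx.reshape(self._shape)


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool2:
    """2x2 max pooling; gradient routed through exact argmax positions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {(h, w)}")
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = blocks.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        onehot = (
            np.arange(4)[None, None, None, None, :] == self._argmax[..., None]
        ).astype(dy.dtype)
        flat = onehot * dy[..., None]
        blocks = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return blocks.reshape(n, h, w, c)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dropout:
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name)) for obj, name in self.params]
        self.v = [np.zeros_like(getattr(obj, name)) for obj, name in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (obj, name) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            update = (self.lr * (self.m[i] / b1t)
                      / (np.sqrt(self.v[i] / b2t) + self.eps))
            setattr(obj, name, getattr(obj, name) - update.astype(g.dtype))
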