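"""Layer primitives with explicit forward/backward passes.

Data layout is ``(N, C, H, W)`` float64.  Convolutions use im2col + matmul;
transposed convolutions are implemented as the adjoint of convolution
(``col2im`` of ``W^T x``), which makes their gradients exact by construction.
"""

from __future__ import annotations

import numpy as np


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold ``(N, C, H, W)`` into ``(N, C*k*k, Ho*Wo)`` patch columns."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def col2im(
    cols: np.ndarray, x_shape: tuple[int, int, int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch columns back to an image."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base: layers expose ``params()``/``grads()`` aligned lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Same-padding convolution (odd kernel), stride 1."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        init: str = "he",
    ) -> None:
        if k % 2 == 0:
            raise ValueError("same padding requires an odd kernel")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2
        fan_in = c_in * k * k
        if init == "he":
            self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        elif init == "zero":
            self.w = np.zeros((c_out, fan_in))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = im2col(x, self.k, 1, self.pad)
        y = np.einsum("of,nfl->nol", self.w, cols, optimize=True) + self.b[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, -1)
        self.dw[...] = np.einsum("nol,nfl->of", dyf, cols, optimize=True)
        self.db[...] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.w, dyf, optimize=True)
        return col2im(dcols, x_shape, self.k, 1, self.pad)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ConvTranspose2D(Layer):
    """Stride-s transposed convolution with kernel 2s, output = s * input.

    Forward is the adjoint of a stride-s convolution, so shapes compose
    exactly with the encoder's pooling pyramid.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        stride: int,
        rng: np.random.Generator,
        init: str = "bilinear",
    ) -> None:
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.k = 2 * stride
        self.pad = stride // 2
        fan = c_out * self.k * self.k
        if init == "bilinear":
            if c_in != c_out:
                raise ValueError("bilinear init needs c_in == c_out")
            self.w = np.zeros((c_in, fan))
            kern = self._bilinear_kernel(self.k).ravel()
            kk = self.k * self.k
            for c in range(c_in):
                self.w[c, c * kk : (c + 1) * kk] = kern
        elif init == "he":
            self.w = rng.normal(0.0, np.sqrt(2.0 / fan), size=(c_in, fan))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @staticmethod
    def _bilinear_kernel(k: int) -> np.ndarray:
        factor = (k + 1) // 2
        center = factor - 1 if k % 2 == 1 else factor - 0.5
        og = np.arange(k, dtype=float)
        f1 = 1 - np.abs(og - center) / factor
        return np.outer(f1, f1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        x_flat = x.reshape(n, c, h * w)
        cols = np.einsum("if,nil->nfl", self.w, x_flat, optimize=True)
        out_shape = (n, self.c_out, self.stride * h, self.stride * w)
        y = col2im(cols, out_shape, self.k, self.stride, self.pad)
        y += self.b[None, :, None, None]
        self._cache = (x_flat, (h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_flat, (h, w) = self._cache
        n = dy.shape[0]
        dcols, _, _ = im2col(dy, self.k, self.stride, self.pad)
        self.dw[...] = np.einsum("nil,nfl->if", x_flat, dcols, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("if,nfl->nil", self.w, dcols, optimize=True)
        return dx.reshape(n, self.c_in, h, w)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims required)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``logits``: (N, C, H, W); ``labels``: (N, H, W) integer class indices.
    """
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.eye(c)[labels].transpose(0, 3, 1, 2)
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum() / (n * h * w))
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
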