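"""Minimal NumPy layers with manual backprop.

Just enough machinery to run the dense-block architecture on a CPU: im2col
convolution, pooling, dropout, a linear head and a softmax cross-entropy
loss node.  Tensors are NCHW ``float32``.  Each layer caches what its
backward pass needs; ``backward`` must be called with the ``dout`` matching
the latest ``forward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Dropout",
    "Linear",
    "softmax",
    "softmax_ce_loss_grad",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int, pad_value: float = 0.0):
    """Unfold (B, C, H, W) into (B*OH*OW, C*k*k) patches."""
    b, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(
            x,
            ((0, 0), (0, 0), (pad, pad), (pad, pad)),
            mode="constant",
            constant_values=pad_value,
        )
    sb, sc, sh, sw = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, k, k, oh, ow),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    cols = view.transpose(0, 4, 5, 1, 2, 3).reshape(b * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Fold (B*OH*OW, C*k*k) gradients back onto the (B, C, H, W) input."""
    b, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    dpad = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(b, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dpad[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, i, j
            ]
    if pad:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


class Layer:
    """Base: layers expose flat parameter/gradient lists for the optimizer."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        bound = float(np.sqrt(6.0 / fan_in))  # He-uniform
        self.w = rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel, kernel)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.stride, self.pad)
        self._cols = cols
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        b = x.shape[0]
        return out.reshape(b, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, f, oh, ow = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(b * oh * ow, f)
        self.dw[...] = (dmat.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dmat.sum(axis=0)
        dcols = dmat @ self.w.reshape(f, -1)
        return _col2im(dcols, self._x_shape, self.kernel, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        self._x_shape = x.shape
        xc = x.reshape(b * c, 1, h, w)
        cols, oh, ow = _im2col(xc, self.kernel, self.stride, self.pad, pad_value=-np.inf)
        self._argmax = cols.argmax(axis=1)
        out = cols[np.arange(cols.shape[0]), self._argmax]
        self._oh, self._ow = oh, ow
        return out.reshape(b, c, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, _, _ = self._x_shape
        flat = dout.reshape(-1)
        dcols = np.zeros((flat.shape[0], self.kernel * self.kernel), dtype=dout.dtype)
        dcols[np.arange(flat.shape[0]), self._argmax] = flat
        dxc = _col2im(
            dcols, (b * c, 1) + self._x_shape[2:], self.kernel, self.stride, self.pad
        )
        return dxc.reshape(self._x_shape)


class AvgPool2d(Layer):
    """Non-overlapping average pool (kernel == stride); odd edges cropped."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.kernel
        self._x_shape = x.shape
        hk, wk = h - h % k, w - w % k
        return x[:, :, :hk, :wk].reshape(b, c, hk // k, k, wk // k, k).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        d = np.repeat(np.repeat(dout, k, axis=2), k, axis=3) / (k * k)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, :, : d.shape[2], : d.shape[3]] = d
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        return np.broadcast_to(dout[:, :, None, None], self._x_shape) / (h * w)


class Dropout(Layer):
    """Inverted dropout; identity at eval time.  Mask drawn from `rng`."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = float(np.sqrt(6.0 / in_dim))
        self.w = rng.uniform(-bound, bound, size=(in_dim, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_ce_loss_grad(
    logits: np.ndarray, labels: np.ndarray, grad_scale: float | None = None
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``grad_scale`` overrides the default 1/batch scaling (used to apply the
    gradual-loss consumption coefficient during an aborted epoch).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    idx = np.arange(n)
    loss = float(-np.log(np.maximum(p[idx, labels], 1e-12)).mean())
    scale = (1.0 / n) if grad_scale is None else grad_scale
    dlogits = p
    dlogits[idx, labels] -= 1.0
    return loss, (dlogits * scale).astype(np.float32)
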