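"""Minimal CNN building blocks in numpy with explicit backpropagation.

Layers operate on NHWC float32 tensors.  Convolutions are stride-1 with
"same" zero-padding and are computed as a sum of shifted matrix products
(one BLAS matmul per kernel offset), which keeps memory flat and lets
single-threaded BLAS do the heavy lifting.  Each layer caches what its
backward pass needs; ``backward`` returns the input gradient and fills
``grads`` keyed like ``params``.

Only what the SE-multi-input classifier needs is implemented; this is not
a general autodiff framework.
"""

from __future__ import annotations

import numpy as np

from .resize import resize_matrix

__all__ = [
    "Conv2D",
    "ReLU",
    "SEBlock",
    "BatchNorm2D",
    "Dense",
    "BicubicResize2D",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

DTYPE = np.float32


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 convolution, odd square kernels.

    Computed as a sum of shifted matrix products — one BLAS matmul per
    kernel offset — which keeps peak memory at a small multiple of the
    feature map instead of materialising a full im2col buffer.
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, rng):
        super().__init__()
        assert kernel % 2 == 1
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = _he_init(rng, (kernel, kernel, c_in, c_out), kernel * kernel * c_in)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x, train=False):
        k, p = self.k, self.k // 2
        B, H, W_, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.zeros((B * H * W_, self.c_out), dtype=DTYPE)
        Wk = self.params["W"]
        for di in range(k):
            for dj in range(k):
                patch = np.ascontiguousarray(xp[:, di : di + H, dj : dj + W_, :]).reshape(-1, C)
                out += patch @ Wk[di, dj]
        out += self.params["b"]
        if train:
            self._cache = xp, (B, H, W_, C)
        return out.reshape(B, H, W_, self.c_out)

    def backward(self, dout):
        xp, (B, H, W_, C) = self._cache
        k, p = self.k, self.k // 2
        d2 = dout.reshape(-1, self.c_out)
        Wk = self.params["W"]
        dW = np.zeros_like(Wk)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = np.ascontiguousarray(xp[:, di : di + H, dj : dj + W_, :]).reshape(-1, C)
                dW[di, dj] = patch.T @ d2
                dxp[:, di : di + H, dj : dj + W_, :] += (d2 @ Wk[di, dj].T).reshape(B, H, W_, C)
        self.grads["W"] = dW
        self.grads["b"] = d2.sum(axis=0)
        return dxp[:, p : p + H, p : p + W_, :] if p else dxp


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pool per channel.  Excite: FC C -> C/r with
    ReLU, FC C/r -> C with sigmoid.  The input is rescaled channel-wise by
    the resulting gate, so output magnitude never exceeds the input's.
    """

    def __init__(self, channels: int, reduced: int, rng):
        super().__init__()
        if reduced >= channels:
            raise ValueError("reduced width must be smaller than the channel count")
        self.c, self.r = channels, reduced
        self.params["W1"] = _he_init(rng, (channels, reduced), channels)
        self.params["b1"] = np.zeros(reduced, dtype=DTYPE)
        self.params["W2"] = _he_init(rng, (reduced, channels), reduced)
        self.params["b2"] = np.zeros(channels, dtype=DTYPE)

    def forward(self, x, train=False):
        if x.shape[-1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[-1]}")
        s = x.mean(axis=(1, 2))                      # (B, C)
        h = s @ self.params["W1"] + self.params["b1"]
        a = np.maximum(h, 0.0)
        z = 1.0 / (1.0 + np.exp(-(a @ self.params["W2"] + self.params["b2"])))
        out = x * z[:, None, None, :]
        if train:
            self._cache = x, s, h, a, z
        return out

    def backward(self, dout):
        x, s, h, a, z = self._cache
        B, H, W_, C = x.shape
        dx = dout * z[:, None, None, :]
        dz = (dout * x).sum(axis=(1, 2))
        dlogit = dz * z * (1.0 - z)
        self.grads["W2"] = a.T @ dlogit
        self.grads["b2"] = dlogit.sum(axis=0)
        da = dlogit @ self.params["W2"].T
        dh = da * (h > 0)
        self.grads["W1"] = s.T @ dh
        self.grads["b1"] = dh.sum(axis=0)
        ds = dh @ self.params["W1"].T
        dx += ds[:, None, None, :] / (H * W_)
        return dx


class BatchNorm2D(Layer):
    """Per-channel normalization with trainable affine and running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = xhat, inv, x.shape
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        n = shape[0] * shape[1] * shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        g = dout * self.params["gamma"]
        dx = inv / n * (n * g - g.sum(axis=(0, 1, 2)) - xhat * (g * xhat).sum(axis=(0, 1, 2)))
        return dx.astype(DTYPE)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        self.params["W"] = _he_init(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class BicubicResize2D(Layer):
    """Fixed bicubic spatial resize of an NHWC feature map (no parameters).

    The resize is linear, so the backward pass is multiplication by the
    transposed interpolation matrices.
    """

    def __init__(self, src_shape: tuple[int, int], dst_shape: tuple[int, int]):
        super().__init__()
        sh, sw = src_shape
        dh, dw = dst_shape
        self.R = (resize_matrix(sh, dh) if sh != dh else np.eye(sh)).astype(DTYPE)
        self.C = (resize_matrix(sw, dw) if sw != dw else np.eye(sw)).astype(DTYPE)

    def forward(self, x, train=False):
        # x: (B, H, W, C) -> (B, dh, dw, C)
        y = np.einsum("ij,bjwc->biwc", self.R, x, optimize=True)
        return np.einsum("kw,bhwc->bhkc", self.C, y, optimize=True).astype(DTYPE)

    def backward(self, dout):
        y = np.einsum("ij,bjwc->biwc", self.R.T.copy(), dout, optimize=True)
        return np.einsum("kw,bhwc->bhkc", self.C.T.copy(), y, optimize=True).astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy against (possibly soft) target distributions.

    Returns (loss, dlogits); the gradient is (p - targets) / batch.
    """
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-(targets * np.log(p + eps)).sum(axis=-1).mean())
    dlogits = ((p - targets) / logits.shape[0]).astype(DTYPE)
    return loss, dlogits


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        if self.lr == 0.0:
            return
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= (self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)).astype(p.dtype)
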