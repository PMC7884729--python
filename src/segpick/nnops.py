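"""Minimal NumPy layer library with hand-written backpropagation.

Implements exactly the operations the segmentation network needs:
same-padded 2D convolution (im2col), batch normalization, ReLU,
max-pooling with argmax indices, index-preserving max-unpooling,
nearest-neighbour upsampling, channel concatenation, softmax
cross-entropy, and an Adam optimizer.  Tensors are NCHW float64.

Each layer caches its forward activations and consumes them in
``backward``; layers are therefore single-use per step, which matches
the strictly sequential training loop that drives them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "MaxUnpool2d",
    "NearestUpsample",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) with same zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, C, k, k, H, W)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    d = dcols.reshape(n, c, k, k, h, w)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, di, dj]
    return dxp[:, :, p : p + h, p : p + w]


class Conv2d:
    """Same-padded 2D convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name: str = "conv"):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(c_out), f"{name}.bias")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col(x, self.k)
        y = np.matmul(self.weight.value, cols)  # (N, c_out, H*W)
        y += self.bias.value[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        dy_mat = dy.reshape(n, self.c_out, h * w)
        self.weight.grad += np.matmul(dy_mat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.bias.grad += dy_mat.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, dy_mat)
        return _col2im(dcols, x_shape, self.k)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not training:
            return dy * g * inv_std[None, :, None, None]
        dxhat = dy * g
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term * inv_std[None, :, None, None]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d:
    """Non-overlapping max pooling by an integer factor, keeping argmaxes."""

    def __init__(self, factor: int = 2):
        self.factor = factor
        self.indices = None  # argmax within each f*f block, flat in-block index
        self._in_shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, h, w = x.shape
        if h % f or w % f:
            raise ValueError(f"spatial dims {h}x{w} not divisible by {f}")
        blocks = x.reshape(n, c, h // f, f, w // f, f).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // f, w // f, f * f)
        self.indices = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self.indices[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, h, w = self._in_shape
        dblocks = np.zeros((n, c, h // f, w // f, f * f))
        np.put_along_axis(dblocks, self.indices[..., None], dy[..., None], axis=-1)
        dx = dblocks.reshape(n, c, h // f, w // f, f, f).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class MaxUnpool2d:
    """Scatter values back to the argmax positions of a paired pooling."""

    def __init__(self, factor: int = 2):
        self.factor = factor
        self._indices = None

    def params(self) -> list[Param]:
        return []

    def forward(self, z: np.ndarray, indices: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, hh, ww = z.shape
        if indices.shape[2:] != (hh, ww):
            raise ValueError("unpool indices do not match input resolution")
        idx = indices
        if idx.shape[1] != c:
            # indices recorded at a different channel width: broadcast-repeat
            idx = np.broadcast_to(idx[:, :1], (n, c, hh, ww))
        blocks = np.zeros((n, c, hh, ww, f * f))
        np.put_along_axis(blocks, idx[..., None], z[..., None], axis=-1)
        self._indices = idx
        out = blocks.reshape(n, c, hh, ww, f, f).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, hh * f, ww * f)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, h, w = dy.shape
        blocks = dy.reshape(n, c, h // f, f, w // f, f).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // f, w // f, f * f)
        return np.take_along_axis(blocks, self._indices[..., None], axis=-1)[..., 0]


class NearestUpsample:
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel weighted softmax cross-entropy.

    ``logits`` is (N, K, H, W); ``target`` is integer (N, H, W); returns
    (mean weighted loss, gradient w.r.t. logits).
    """
    n, k, h, w = logits.shape
    probs = softmax(logits, axis=1)
    onehot = np.eye(k)[target].transpose(0, 3, 1, 2)  # (N, K, H, W)
    wpix = class_weights[target]  # (N, H, W)
    total_w = max(wpix.sum(), 1e-12)
    logp = np.log(np.clip(probs, 1e-12, None))
    loss = -(wpix * (onehot * logp).sum(axis=1)).sum() / total_w
    grad = (probs - onehot) * wpix[:, None] / total_w
    return float(loss), grad


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
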