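"""A small float32 neural-network engine with explicit backpropagation.

Only the pieces the contact predictor needs are implemented: 1-D (dilated)
convolution with same-padding, ReLU, non-overlapping max pooling, inverted
dropout, WaveNet-style gated residual blocks, a dense head, and an Adam
optimizer with coupled L2 regularization.  Layers are functional: ``forward``
returns ``(y, cache)`` and ``backward`` consumes the cache and *accumulates*
parameter gradients, so several forward passes (e.g. the two haplotypes of a
training window) can share one backward sweep.

Activations are ``(length, channels)`` arrays — position-major, so the
im2col window copies and the GEMMs both run on contiguous memory.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution with optional dilation.

    Weight shape is (k, c_in, c_out), tap-major so the im2col matmul is a
    single GEMM.  He-style initialization.  Set ``input_grad = False`` on a
    first layer to skip the (useless) gradient w.r.t. the network input.
    """

    def __init__(self, c_in: int, c_out: int, k: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * k))
        self.k, self.c_in, self.c_out, self.dilation = k, c_in, c_out, dilation
        self.w = Param(rng.normal(0.0, scale, (k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        span = dilation * (k - 1)
        self.pad_left = span // 2
        self.pad_right = span - self.pad_left
        self.input_grad = True

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        L, c_in = x.shape
        if self.k == 1:
            y = x @ self.w.value[0] + self.b.value
            return y, (x, L)
        xp = np.pad(x, ((self.pad_left, self.pad_right), (0, 0)))
        cols = np.empty((L, self.k * c_in), dtype=F32)
        for t in range(self.k):
            off = t * self.dilation
            cols[:, t * c_in : (t + 1) * c_in] = xp[off : off + L]
        y = cols @ self.w.value.reshape(self.k * c_in, self.c_out) + self.b.value
        return y, (cols, L)

    def backward(self, cache, dy):
        cols, L = cache
        dy = np.ascontiguousarray(dy, dtype=F32)
        if self.k == 1:
            self.w.grad[0] += cols.T @ dy
            self.b.grad += dy.sum(axis=0)
            if not self.input_grad:
                return None
            return dy @ self.w.value[0].T
        self.w.grad += (cols.T @ dy).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=0)
        if not self.input_grad:
            return None
        dxp = np.zeros((L + self.pad_left + self.pad_right, self.c_in), dtype=F32)
        for t in range(self.k):
            off = t * self.dilation
            dxp[off : off + L] += dy @ self.w.value[t].T
        return dxp[self.pad_left : self.pad_left + L]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        y = np.maximum(x, 0)
        return y, (x > 0)

    def backward(self, cache, dy):
        return dy * cache


class MaxPool(Layer):
    """Non-overlapping max pooling over positions; length must divide evenly."""

    def __init__(self, width: int):
        self.width = width

    def forward(self, x, train=False, rng=None):
        L, c = x.shape
        if L % self.width:
            raise ValueError(f"length {L} not divisible by pool width {self.width}")
        xr = x.reshape(L // self.width, self.width, c)
        # argmax bookkeeping is deferred to backward: inference never pays it
        return xr.max(axis=1), xr

    def backward(self, cache, dy):
        xr = cache
        idx = xr.argmax(axis=1)
        dxr = np.zeros_like(xr, dtype=F32)
        np.put_along_axis(dxr, idx[:, None, :], dy[:, None, :], axis=1)
        return dxr.reshape(xr.shape[0] * xr.shape[1], xr.shape[2])


class Dropout(Layer):
    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= self.rate).astype(F32) / F32(1.0 - self.rate)
        return x * mask, mask

    def backward(self, cache, dy):
        if cache is None:
            return dy
        return dy * cache


class GatedBlock(Layer):
    """Residual gated dilated convolution: x + tanh(conv_f x) * sigmoid(conv_g x)."""

    def __init__(self, channels: int, k: int, dilation: int, rng):
        self.f = Conv1d(channels, channels, k, dilation, rng)
        self.g = Conv1d(channels, channels, k, dilation, rng)

    def parameters(self):
        return self.f.parameters() + self.g.parameters()

    def forward(self, x, train=False, rng=None):
        a, ca = self.f.forward(x)
        b, cb = self.g.forward(x)
        th = np.tanh(a)
        sg = 0.5 * (1.0 + np.tanh(0.5 * b))  # sigmoid, overflow-free
        y = x + th * sg
        return y, (ca, cb, th, sg)

    def backward(self, cache, dy):
        ca, cb, th, sg = cache
        da = dy * sg * (1.0 - th * th)
        db = dy * th * sg * (1.0 - sg)
        return dy + self.f.backward(ca, da) + self.g.backward(cb, db)


class Dense(Layer):
    """Fully connected map from a flattened (length, channels) feature map."""

    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, (n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        v = np.ascontiguousarray(x, dtype=F32).ravel()
        return self.w.value @ v + self.b.value, (v, x.shape)

    def backward(self, cache, dy):
        v, shape = cache
        self.w.grad += np.outer(dy, v)
        self.b.grad += dy
        return (self.w.value.T @ dy.astype(F32)).reshape(shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend(lay.parameters())
        return out

    def forward(self, x, train=False, rng=None):
        caches = []
        for lay in self.layers:
            x, c = lay.forward(x, train=train, rng=rng)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for lay, c in zip(reversed(self.layers), reversed(caches)):
            dy = lay.backward(c, dy)
            if dy is None:  # a frozen/first layer cut the gradient path
                break
        return dy


class Adam:
    """Adam with coupled L2 regularization (decay added to the gradient)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, eps: float = 0.1,
                 l2: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999):
        self.params = params
        self.lr, self.eps, self.l2 = lr, eps, l2
        self.beta1, self.beta2 = beta1, beta2
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p in self.params:
            g = p.grad + F32(self.l2) * p.value
            p.m *= b1
            p.m += (1 - b1) * g
            p.v *= b2
            p.v += (1 - b2) * g * g
            p.value -= F32(self.lr) * (p.m / bc1) / (np.sqrt(p.v / bc2) + F32(self.eps))

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
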