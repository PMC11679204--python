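"""A small NumPy neural-network engine for EEG convolutional models.

Implements exactly the layer kinds the dual-branch attention architectures
need — temporal convolutions, spatial depthwise convolutions, separable
temporal convolutions, batch normalization, ELU, average pooling, dropout,
CBAM channel/spatial attention, and a dense softmax head — each with a
hand-written backward pass, plus an Adam optimizer that honours per-parameter
freezing.  Tensors are float32 in (batch, maps, electrodes, time) layout.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator and freeze flag."""

    __slots__ = ("name", "value", "grad", "frozen")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.frozen = False

    @property
    def size(self) -> int:
        return int(self.value.size)


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _win(x: np.ndarray, k: int, pad_l: int, pad_r: int) -> np.ndarray:
    """Sliding windows of width k along the last axis after padding."""
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad_l, pad_r)])
    return sliding_window_view(xp, k, axis=-1)


class Layer:
    params: List[Param]

    def __init__(self):
        self.params = []

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover
        raise NotImplementedError


class TemporalConv(Layer):
    """Conv2D with a (1, K) kernel, 'same' padding along time, no bias."""

    def __init__(self, name, cin, cout, k, rng):
        super().__init__()
        self.k, self.cin, self.cout = k, cin, cout
        self.pad_l, self.pad_r = (k - 1) // 2, k // 2
        w = _glorot(rng, (cout, cin, k), fan_in=cin * k, fan_out=cout * k)
        self.W = Param(f"{name}.W", w)
        self.params = [self.W]

    def forward(self, x, training=False, rng=None):
        self._x = x
        win = _win(x, self.k, self.pad_l, self.pad_r)  # (n,c,h,w,k)
        return np.einsum("nchwk,ock->nohw", win, self.W.value).astype(np.float32)

    def backward(self, g):
        win = _win(self._x, self.k, self.pad_l, self.pad_r)
        self.W.grad += np.einsum("nchwk,nohw->ock", win, g)
        gw = _win(g, self.k, self.pad_r, self.pad_l)
        return np.einsum("nohwk,ock->nchw", gw, self.W.value[:, :, ::-1]).astype(np.float32)


class SpatialDepthwiseConv(Layer):
    """DepthwiseConv2D with a (H, 1) kernel and depth multiplier D.

    Collapses the electrode axis: (n, cin, H, w) -> (n, cin*D, 1, w).
    """

    def __init__(self, name, cin, h, d, rng):
        super().__init__()
        self.cin, self.h, self.d = cin, h, d
        w = _glorot(rng, (cin, d, h), fan_in=h, fan_out=d)
        self.W = Param(f"{name}.W", w)
        self.params = [self.W]

    def forward(self, x, training=False, rng=None):
        self._x = x
        out = np.einsum("niht,idh->nidt", x, self.W.value)
        n, _, _, t = x.shape
        return out.reshape(n, self.cin * self.d, 1, t).astype(np.float32)

    def backward(self, g):
        n, _, _, t = self._x.shape
        g = g.reshape(n, self.cin, self.d, t)
        self.W.grad += np.einsum("niht,nidt->idh", self._x, g)
        return np.einsum("nidt,idh->niht", g, self.W.value).astype(np.float32)


class FanOut(Layer):
    """Depthwise (1, 1) conv with multiplier D on a single input map.

    Expands (n, 1, H, W) into (n, D, H, W) scaled copies — the entry point
    of an overcomplete temporal filter bank whose kernels live in the
    following separable convolution.
    """

    def __init__(self, name, d, rng):
        super().__init__()
        self.d = d
        self.W = Param(f"{name}.W", _glorot(rng, (d,), 1, d))
        self.params = [self.W]

    def forward(self, x, training=False, rng=None):
        self._x = x  # (n, 1, H, W)
        return x * self.W.value[None, :, None, None]

    def backward(self, g):
        self.W.grad += np.einsum("ndhw,nehw->d", g, self._x)
        return (g * self.W.value[None, :, None, None]).sum(axis=1, keepdims=True)


class ElectrodeMean(Layer):
    """Parameter-free average over the electrode axis: (n,c,H,w) -> (n,c,1,w)."""

    def forward(self, x, training=False, rng=None):
        self._h = x.shape[2]
        return x.mean(axis=2, keepdims=True)

    def backward(self, g):
        return np.repeat(g / self._h, self._h, axis=2)


class ChannelScale(Layer):
    """Degenerate (1, 1) depthwise conv: one multiplicative weight per map."""

    def __init__(self, name, c):
        super().__init__()
        self.W = Param(f"{name}.W", np.ones(c, dtype=np.float32))
        self.params = [self.W]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x * self.W.value[None, :, None, None]

    def backward(self, g):
        self.W.grad += np.einsum("nchw,nchw->c", g, self._x)
        return g * self.W.value[None, :, None, None]


class SeparableTemporalConv(Layer):
    """SeparableConv2D with a (1, K) kernel: depthwise then pointwise, no bias."""

    def __init__(self, name, cin, cout, k, rng):
        super().__init__()
        self.k, self.cin, self.cout = k, cin, cout
        self.pad_l, self.pad_r = (k - 1) // 2, k // 2
        self.Wd = Param(f"{name}.Wd", _glorot(rng, (cin, k), k, k))
        self.Wp = Param(f"{name}.Wp", _glorot(rng, (cin, cout), cin, cout))
        self.params = [self.Wd, self.Wp]

    def forward(self, x, training=False, rng=None):
        self._x = x
        win = _win(x, self.k, self.pad_l, self.pad_r)
        self._xd = np.einsum("nchwk,ck->nchw", win, self.Wd.value).astype(np.float32)
        return np.einsum("nchw,co->nohw", self._xd, self.Wp.value).astype(np.float32)

    def backward(self, g):
        self.Wp.grad += np.einsum("nchw,nohw->co", self._xd, g)
        gd = np.einsum("nohw,co->nchw", g, self.Wp.value)
        win = _win(self._x, self.k, self.pad_l, self.pad_r)
        self.Wd.grad += np.einsum("nchwk,nchw->ck", win, gd)
        gw = _win(gd, self.k, self.pad_r, self.pad_l)
        return np.einsum("nchwk,ck->nchw", gw, self.Wd.value[:, ::-1]).astype(np.float32)


class PointwiseConv(Layer):
    """1x1 Conv2D (channel mixing), no bias."""

    def __init__(self, name, cin, cout, rng):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.W = Param(f"{name}.W", _glorot(rng, (cin, cout), cin, cout))
        self.params = [self.W]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return np.einsum("nchw,co->nohw", x, self.W.value).astype(np.float32)

    def backward(self, g):
        self.W.grad += np.einsum("nchw,nohw->co", self._x, g)
        return np.einsum("nohw,co->nchw", g, self.W.value).astype(np.float32)


class BatchNorm(Layer):
    """Per-map batch normalization over (batch, electrodes, time)."""

    def __init__(self, name, c, eps=1e-3, momentum=0.9):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=np.float32))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.frozen = False  # frozen BN also pins its running statistics

    def forward(self, x, training=False, rng=None):
        if training and not self.frozen:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            self._batch = True
        else:
            mean, var = self.running_mean, self.running_var
            self._batch = False
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = ((x - mean[None, :, None, None])
                      / self._std[None, :, None, None]).astype(np.float32)
        return (self.gamma.value[None, :, None, None] * self._xhat
                + self.beta.value[None, :, None, None])

    def backward(self, g):
        self.gamma.grad += np.einsum("nchw,nchw->c", g, self._xhat)
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gx = g * self.gamma.value[None, :, None, None]
        if not self._batch:
            return (gx / self._std[None, :, None, None]).astype(np.float32)
        m = g.shape[0] * g.shape[2] * g.shape[3]
        s = self._std[None, :, None, None]
        t1 = gx / s
        t2 = gx.sum(axis=(0, 2, 3))[None, :, None, None] / (m * s)
        t3 = (self._xhat / (m * s)
              * np.einsum("nchw,nchw->c", gx, self._xhat)[None, :, None, None])
        return (t1 - t2 - t3).astype(np.float32)


class ELU(Layer):
    def forward(self, x, training=False, rng=None):
        self._neg = x < 0
        self._ex = np.where(self._neg, np.exp(np.minimum(x, 0.0)), 1.0).astype(np.float32)
        return np.where(self._neg, self._ex - 1.0, x).astype(np.float32)

    def backward(self, g):
        return np.where(self._neg, g * self._ex, g).astype(np.float32)


class AvgPoolTime(Layer):
    """Average pooling (1, P) with 'valid' truncation along time."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        self._w = w
        wo = w // self.p
        return x[:, :, :, : wo * self.p].reshape(n, c, h, wo, self.p).mean(axis=4)

    def backward(self, g):
        n, c, h, wo = g.shape
        gx = np.zeros((n, c, h, self._w), dtype=np.float32)
        gx[:, :, :, : wo * self.p] = np.repeat(g / self.p, self.p, axis=3)
        return gx


class Dropout(Layer):
    def __init__(self, rate=0.25):
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class CBAMChannel(Layer):
    """Channel attention: global avg+max pooling through a shared MLP.

    The bottleneck width is configurable; gates are sigmoid of the summed
    excitations.  Parameters are split into 'reduce' (W1, b1) and 'expand'
    (W2, b2) groups so a freeze boundary can address them separately.
    """

    def __init__(self, name, c, hidden, rng):
        super().__init__()
        self.c, self.hidden = c, hidden
        self.W1 = Param(f"{name}.W1", _glorot(rng, (c, hidden), c, hidden))
        self.b1 = Param(f"{name}.b1", np.zeros(hidden, dtype=np.float32))
        self.W2 = Param(f"{name}.W2", _glorot(rng, (hidden, c), hidden, c))
        self.b2 = Param(f"{name}.b2", np.zeros(c, dtype=np.float32))
        self.params = [self.W1, self.b1, self.W2, self.b2]

    def _mlp(self, s):
        h = np.maximum(s @ self.W1.value + self.b1.value, 0.0)
        return h, h @ self.W2.value + self.b2.value

    def forward(self, x, training=False, rng=None):
        n, c, h, w = x.shape
        self._x = x
        self._hw = h * w
        flat = x.reshape(n, c, h * w)
        self._savg = flat.mean(axis=2)
        self._amax = flat.argmax(axis=2)
        self._smax = np.take_along_axis(flat, self._amax[:, :, None], axis=2)[:, :, 0]
        self._h_avg, e_avg = self._mlp(self._savg)
        self._h_max, e_max = self._mlp(self._smax)
        self._gate = _sigmoid(e_avg + e_max).astype(np.float32)
        return x * self._gate[:, :, None, None]

    def backward(self, g):
        dgate = np.einsum("nchw,nchw->nc", g, self._x)
        gx = g * self._gate[:, :, None, None]
        de = dgate * self._gate * (1.0 - self._gate)
        ds = []
        for hcache, s in ((self._h_avg, self._savg), (self._h_max, self._smax)):
            self.W2.grad += hcache.T @ de
            self.b2.grad += de.sum(axis=0)
            dh = (de @ self.W2.value.T) * (hcache > 0)
            self.W1.grad += s.T @ dh
            self.b1.grad += dh.sum(axis=0)
            ds.append(dh @ self.W1.value.T)
        n, c, h, w = self._x.shape
        gx = gx + (ds[0] / self._hw)[:, :, None, None]
        gmax = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(gmax, self._amax[:, :, None], ds[1][:, :, None], axis=2)
        return (gx + gmax.reshape(n, c, h, w)).astype(np.float32)


class CBAMSpatial(Layer):
    """Spatial attention: channel mean/max maps through a (1, 7) conv gate."""

    def __init__(self, name, rng, k=7):
        super().__init__()
        self.k = k
        self.pad_l, self.pad_r = (k - 1) // 2, k // 2
        self.W = Param(f"{name}.W", _glorot(rng, (1, 2, k), 2 * k, k))
        self.b = Param(f"{name}.b", np.zeros(1, dtype=np.float32))
        self.params = [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._amax = x.argmax(axis=1)
        mmax = np.take_along_axis(x, self._amax[:, None], axis=1)
        self._cat = np.concatenate([x.mean(axis=1, keepdims=True), mmax], axis=1)
        win = _win(self._cat, self.k, self.pad_l, self.pad_r)
        z = np.einsum("nchwk,ock->nohw", win, self.W.value) + self.b.value
        self._gate = _sigmoid(z).astype(np.float32)
        return x * self._gate

    def backward(self, g):
        dgate = (g * self._x).sum(axis=1, keepdims=True)
        gx = g * self._gate
        dz = dgate * self._gate * (1.0 - self._gate)
        win = _win(self._cat, self.k, self.pad_l, self.pad_r)
        self.W.grad += np.einsum("nchwk,nohw->ock", win, dz)
        self.b.grad += dz.sum()
        gw = _win(dz, self.k, self.pad_r, self.pad_l)
        dcat = np.einsum("nohwk,ock->nchw", gw, self.W.value[:, :, ::-1])
        n, c = self._x.shape[:2]
        gx = gx + dcat[:, :1] / c
        gmax = np.zeros_like(self._x)
        np.put_along_axis(gmax, self._amax[:, None], dcat[:, 1:2], axis=1)
        return (gx + gmax).astype(np.float32)


class Dense(Layer):
    def __init__(self, name, fin, fout, rng):
        super().__init__()
        self.W = Param(f"{name}.W", _glorot(rng, (fin, fout), fin, fout))
        self.b = Param(f"{name}.b", np.zeros(fout, dtype=np.float32))
        self.params = [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return (g @ self.W.value.T).astype(np.float32)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=1, keepdims=True)).astype(np.float32)


def cross_entropy(probs: np.ndarray, y_idx: np.ndarray) -> float:
    return float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())


class Adam:
    """Adam over a parameter list; frozen parameters are never touched."""

    def __init__(self, params: List[Param], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: Dict[int, Tuple[np.ndarray, np.ndarray]] = {
            id(p): (np.zeros_like(p.value), np.zeros_like(p.value)) for p in params
        }

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in self.params:
            if p.frozen:
                continue
            m, v = self.state[id(p)]
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
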