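"""Compact reverse-mode autodiff core for the restoration networks.

A tape-based scalar-loss engine over numpy arrays, providing exactly the
operations the encoder-decoder networks need: 3x3 convolution, 2x2 transposed
convolution, 2x2 max pooling, batch normalization, ReLU/sigmoid, channel
concatenation, forward differences (for the total-variation regularizer) and
the usual arithmetic/reductions, plus an Adam optimizer.

All computation is float64 and single-threaded-deterministic: identical seeds
and inputs reproduce bit-identical parameters and losses.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers --------------------------------------

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward, track: bool) -> Tensor:
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = False
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- arithmetic -----------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    track = _needs_grad(a, b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward, track)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    track = _needs_grad(a, b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward, track)


def square(a) -> Tensor:
    a = _as_tensor(a)
    track = _needs_grad(a)

    def backward(g):
        a._accumulate(2.0 * a.data * g)

    return _make(a.data * a.data, (a,), backward, track)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    track = _needs_grad(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g / (2.0 * np.maximum(out_data, 1e-300)))

    return _make(out_data, (a,), backward, track)


def mean(a, axis=None) -> Tensor:
    a = _as_tensor(a)
    track = _needs_grad(a)
    out_data = a.data.mean(axis=axis)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])

    def backward(g):
        if axis is None:
            a._accumulate(np.full_like(a.data, 1.0 / n) * g)
        else:
            g_exp = np.expand_dims(g, axis=axis)
            a._accumulate(np.broadcast_to(g_exp, a.data.shape) / n)

    return _make(out_data, (a,), backward, track)


def total_sum(a) -> Tensor:
    a = _as_tensor(a)
    track = _needs_grad(a)

    def backward(g):
        a._accumulate(np.full_like(a.data, 1.0) * g)

    return _make(a.data.sum(), (a,), backward, track)


# -- nonlinearities -------------------------------------------------------


def relu(a) -> Tensor:
    a = _as_tensor(a)
    track = _needs_grad(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward, track)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    track = _needs_grad(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward, track)


# -- structural ops -------------------------------------------------------


def concat_channels(tensors) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    track = _needs_grad(*tensors)
    sizes = [t.data.shape[1] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            t._accumulate(g[:, lo:hi])

    return _make(np.concatenate([t.data for t in tensors], axis=1),
                 tensors, backward, track)


def forward_diff(a, axis: int) -> Tensor:
    """Forward difference along `axis` with replicate boundary (last slice 0).

    Output has the same shape as the input; used by the TV regularizer.
    """
    a = _as_tensor(a)
    track = _needs_grad(a)
    d = np.zeros_like(a.data)
    sl_hi = [slice(None)] * a.data.ndim
    sl_lo = [slice(None)] * a.data.ndim
    sl_out = [slice(None)] * a.data.ndim
    n = a.data.shape[axis]
    sl_hi[axis] = slice(1, n)
    sl_lo[axis] = slice(0, n - 1)
    sl_out[axis] = slice(0, n - 1)
    d[tuple(sl_out)] = a.data[tuple(sl_hi)] - a.data[tuple(sl_lo)]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[tuple(sl_hi)] += g[tuple(sl_out)]
        ga[tuple(sl_lo)] -= g[tuple(sl_out)]
        a._accumulate(ga)

    return _make(d, (a,), backward, track)


# -- convolution family ---------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H*W) for stride-1 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, h, w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
    return cols.reshape(n, c * kh * kw, h * w)


def _col2im(cols: np.ndarray, shape, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    cols = cols.reshape(n, c, kh, kw, h, w)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x, w, b, pad: int = 1) -> Tensor:
    """Stride-1 'same' 2D convolution; x:(N,C,H,W), w:(O,C,kh,kw), b:(O,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    track = _needs_grad(x, w, b)
    n, c, h, wid = x.data.shape
    o, _, kh, kw = w.data.shape
    cols = _im2col(x.data, kh, kw, pad)              # (N, CKK, HW)
    w2 = w.data.reshape(o, -1)                       # (O, CKK)
    out = (w2 @ cols).reshape(n, o, h, wid) + b.data.reshape(1, o, 1, 1)

    def backward(g):
        gm = g.reshape(n, o, h * wid)                # (N,O,HW)
        w._accumulate(np.einsum("nof,ncf->oc", gm, cols,
                                optimize=True).reshape(w.data.shape))
        b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.matmul(w2.T[None], gm)            # (N,CKK,HW)
        x._accumulate(_col2im(dcols, x.data.shape, kh, kw, pad))

    return _make(out, (x, w, b), backward, track)


def conv_transpose2d(x, w, b) -> Tensor:
    """2x upsampling transposed convolution, kernel 2 stride 2.

    x:(N,C,H,W), w:(C,O,2,2), b:(O,) -> (N,O,2H,2W).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    track = _needs_grad(x, w, b)
    n, c, h, wid = x.data.shape
    o = w.data.shape[1]
    tmp = np.einsum("ncij,coab->noiajb", x.data, w.data, optimize=True)
    out = tmp.reshape(n, o, 2 * h, 2 * wid) + b.data.reshape(1, o, 1, 1)

    def backward(g):
        g6 = g.reshape(n, o, h, 2, wid, 2)
        x._accumulate(np.einsum("noiajb,coab->ncij", g6, w.data,
                                optimize=True))
        w._accumulate(np.einsum("ncij,noiajb->coab", x.data, g6,
                                optimize=True))
        b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, (x, w, b), backward, track)


def maxpool2d(x) -> Tensor:
    """2x2 max pooling, stride 2; requires even H and W."""
    x = _as_tensor(x)
    track = _needs_grad(x)
    n, c, h, w = x.data.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    r = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gr.reshape(n, c, h, w))

    return _make(out, (x,), backward, track)


def batchnorm2d(x, gamma, beta, state: dict, training: bool,
                momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N,H,W).

    `state` holds running_mean / running_var, updated in training mode.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    track = _needs_grad(x, gamma, beta)
    c = x.data.shape[1]
    g4 = gamma.data.reshape(1, c, 1, 1)
    b4 = beta.data.reshape(1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        state["running_mean"] = ((1 - momentum) * state["running_mean"]
                                 + momentum * mu.ravel())
        state["running_var"] = ((1 - momentum) * state["running_var"]
                                + momentum * var.ravel())
    else:
        mu = state["running_mean"].reshape(1, c, 1, 1)
        var = state["running_var"].reshape(1, c, 1, 1)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = g4 * xhat + b4

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gx_hat = g * g4
            t1 = gx_hat - gx_hat.mean(axis=(0, 2, 3), keepdims=True)
            t2 = xhat * (gx_hat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accumulate(inv_std * (t1 - t2))
            del m
        else:
            x._accumulate(g * g4 * inv_std)

    return _make(out, (x, gamma, beta), backward, track)


# -- parameters and optimizer ---------------------------------------------


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
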