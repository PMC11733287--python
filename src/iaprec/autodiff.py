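"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for 1-D convolutional encoder/decoder networks
with custom composite losses: tensors wrap float32 numpy arrays and
record a tape of backward closures.  Supported primitives: broadcasted
arithmetic, matmul, strided 1-D convolution (as a sum of shifted thin
matrix products), nearest/linear upsampling, batch normalization, the
usual pointwise nonlinearities, slicing, concatenation and full
reductions.

Design notes
------------
* Gradients accumulate into ``.grad``; call :func:`backward` on a
  scalar tensor.
* Broadcasting in elementwise ops is undone in the backward pass by
  summing over the broadcast axes.
* ``clamp_away_from_zero`` uses a straight-through gradient: it guards
  divisions in physics residuals without killing the gradient signal.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._backward = None
        self._parents = _parents
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- operators ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, reciprocal(_as_tensor(other)))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), reciprocal(self))

    def __neg__(self):
        return neg(self)

    def __getitem__(self, sl):
        return tslice(self, sl)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=DTYPE, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def backward(out: Tensor) -> None:
    """Reverse-mode sweep from a scalar tensor."""
    if out.data.size != 1:
        raise ValueError("backward() expects a scalar loss tensor")
    topo: list[Tensor] = []
    seen = set()

    def visit(t: Tensor):
        stack = [(t, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

    visit(out)
    out.grad = np.ones_like(out.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


# -- elementwise primitives -------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, _parents=(a,))
    out._backward = lambda g: _accum(a, -g)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.data
    out = Tensor(inv, _parents=(a,))
    out._backward = lambda g: _accum(a, -g * inv * inv)
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data * a.data, _parents=(a,))
    out._backward = lambda g: _accum(a, 2.0 * g * a.data)
    return out


def absolute(a: Tensor) -> Tensor:
    out = Tensor(np.abs(a.data), _parents=(a,))
    out._backward = lambda g: _accum(a, g * np.sign(a.data))
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), _parents=(a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, _parents=(a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
    out = Tensor(s, _parents=(a,))
    out._backward = lambda g: _accum(a, g * s * (1.0 - s))
    return out


def softplus(a: Tensor) -> Tensor:
    z = a.data
    val = np.where(z > 20, z, np.log1p(np.exp(np.minimum(z, 20.0))))
    out = Tensor(val, _parents=(a,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    out._backward = lambda g: _accum(a, g * sig)
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data), _parents=(a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * take_a, a.data.shape))
        _accum(b, _unbroadcast(g * ~take_a, b.data.shape))

    out._backward = bw
    return out


def clamp_away_from_zero(a: Tensor, eps: float) -> Tensor:
    """max(|x|, eps) with x's sign, straight-through gradient."""
    d = a.data
    val = np.where(np.abs(d) < eps, np.where(d < 0, -eps, eps), d)
    out = Tensor(val, _parents=(a,))
    out._backward = lambda g: _accum(a, g)
    return out


def mean(a: Tensor) -> Tensor:
    out = Tensor(np.mean(a.data), _parents=(a,))
    n = a.data.size
    out._backward = lambda g: _accum(a, np.broadcast_to(g / n, a.data.shape))
    return out


def tsum(a: Tensor) -> Tensor:
    out = Tensor(np.sum(a.data), _parents=(a,))
    out._backward = lambda g: _accum(a, np.broadcast_to(g, a.data.shape))
    return out


def mean_axis(a: Tensor, axis: tuple, keepdims: bool = True) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    out = Tensor(out_data, _parents=(a,))
    n = a.data.size / out_data.size

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g / n, a.data.shape))

    out._backward = bw
    return out


def tslice(a: Tensor, sl) -> Tensor:
    out = Tensor(a.data[sl], _parents=(a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        _accum(a, full)

    out._backward = bw
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), _parents=(a,))
    out._backward = lambda g: _accum(a, g.reshape(a.data.shape))
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = bw
    return out


# -- structural ops ---------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """1-D convolution on (batch, length, channels) with 'same'-style
    padding and ceil-division output length.

    ``w`` has shape (K * C_in, C_out), k-major; ``b`` shape (C_out,).
    Implemented as a sum over kernel taps of shifted (B*L, C) @ (C, Cout)
    products, which avoids materialising a K-fold im2col buffer.
    """
    B, L, C = x.data.shape
    KC, Cout = w.data.shape
    K = KC // C
    out_len = -(-L // stride)
    pad_total = max((out_len - 1) * stride + K - L, 0)
    pl = pad_total // 2
    pr = pad_total - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    wk = w.data.reshape(K, C, Cout)
    y = np.empty((B, out_len, Cout), dtype=DTYPE)
    y[:] = b.data
    yf = y.reshape(B * out_len, Cout)
    span = stride * out_len
    for k in range(K):
        xk = xp[:, k : k + span : stride, :]
        if stride > 1:
            xk = np.ascontiguousarray(xk)
        yf += xk.reshape(B * out_len, C) @ wk[k]
    out = Tensor(y, _parents=(x, w, b))

    def bw(g):
        g2 = g.reshape(B * out_len, Cout)
        if w.requires_grad:
            dw = np.empty_like(wk)
            for k in range(K):
                xk = xp[:, k : k + span : stride, :]
                if stride > 1:
                    xk = np.ascontiguousarray(xk)
                dw[k] = xk.reshape(B * out_len, C).T @ g2
            _accum(w, dw.reshape(KC, Cout))
        _accum(b, g2.sum(axis=0))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for k in range(K):
                dk = (g2 @ wk[k].T).reshape(B, out_len, C)
                dxp[:, k : k + span : stride, :] += dk
            _accum(x, dxp[:, pl : pl + L, :])

    out._backward = bw
    return out


def upsample_linear(x: Tensor, factor: int, target_len: int) -> Tensor:
    """Linear interpolation along the length axis, cropped to target_len.

    Output position j maps to source position j/factor; the last source
    sample is clamped.  Avoids the staircase of nearest-neighbour
    upsampling, which blunts sharp reconstructed waveforms.
    """
    B, L, C = x.data.shape
    r = factor
    k = (np.arange(r, dtype=DTYPE) / r)[None, None, :, None]
    x_next = np.concatenate([x.data[:, 1:, :], x.data[:, -1:, :]], axis=1)
    y = (x.data[:, :, None, :] * (1.0 - k) + x_next[:, :, None, :] * k).reshape(B, L * r, C)
    if y.shape[1] < target_len:
        raise ValueError("upsample factor too small for target length")
    out = Tensor(np.ascontiguousarray(y[:, :target_len, :]), _parents=(x,))

    def bw(g):
        full = np.zeros((B, L * r, C), dtype=DTYPE)
        full[:, :target_len, :] = g
        g4 = full.reshape(B, L, r, C)
        c1 = (g4 * (1.0 - k)).sum(axis=2)
        c2 = (g4 * k).sum(axis=2)
        dx = c1
        dx[:, 1:, :] += c2[:, :-1, :]
        dx[:, -1, :] += c2[:, -1, :]
        _accum(x, dx)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int, target_len: int) -> Tensor:
    """Repeat along the length axis then crop to ``target_len``."""
    B, L, C = x.data.shape
    rep = np.repeat(x.data, factor, axis=1)
    if rep.shape[1] < target_len:
        raise ValueError("upsample factor too small for target length")
    out = Tensor(rep[:, :target_len, :], _parents=(x,))

    def bw(g):
        full = np.zeros((B, L * factor, C), dtype=DTYPE)
        full[:, :target_len, :] = g
        _accum(x, full.reshape(B, L, factor, C).sum(axis=2))

    out._backward = bw
    return out


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (batch, length) per channel."""
    if training:
        mu = x.data.mean(axis=(0, 1))
        var = x.data.var(axis=(0, 1))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu = running["mean"]
        var = running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))

    def bw(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 1)))
        _accum(beta, g.sum(axis=(0, 1)))
        if x.requires_grad:
            if training:
                n = x.data.shape[0] * x.data.shape[1]
                gx = g * gamma.data
                dx = (
                    gx - gx.mean(axis=(0, 1)) - xhat * (gx * xhat).mean(axis=(0, 1))
                ) * inv
                _accum(x, dx.astype(DTYPE))
            else:
                _accum(x, (g * gamma.data * inv).astype(DTYPE))

    out._backward = bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, L, C) -> (B, C)."""
    B, L, C = x.data.shape
    out = Tensor(x.data.mean(axis=1), _parents=(x,))
    out._backward = lambda g: _accum(
        x, np.broadcast_to(g[:, None, :] / L, x.data.shape)
    )
    return out


# -- parameters and optimiser -----------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with the standard bias correction; deterministic."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


def he_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)
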