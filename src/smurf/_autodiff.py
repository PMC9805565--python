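"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to backpropagate through the smooth-alignment dynamic
program, the convolutional encoder and the MRF masked-language-model loss:
a tape of `Tensor` nodes, each holding a value, its parents and a vjp
(vector-Jacobian product) closure.  First-order only; gradients are plain
numpy arrays.  All floats are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "var", "const", "grad",
    "exp", "log", "tsum", "matmul", "transpose", "reshape",
    "concat", "stack", "where", "take_cols", "put_cols",
    "lse", "lse_axis", "log_softmax", "softmax",
]


class Tensor:
    """Node in the computation graph (value + provenance)."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjp = vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def var(data):
    """Leaf tensor that gradients are taken with respect to."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def const(data):
    return data if isinstance(data, Tensor) else Tensor(data)


def _as(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = len(shape)
    while g.ndim > nd:
        g = g.sum(axis=0)
    axes = tuple(i for i in range(nd) if shape[i] == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- primitive ops ------------------------------------------------------

def add(x, y):
    x, y = _as(x), _as(y)

    def vjp(g):
        return _unbroadcast(g, x.data.shape), _unbroadcast(g, y.data.shape)

    return Tensor(x.data + y.data, (x, y), vjp)


def mul(x, y):
    x, y = _as(x), _as(y)

    def vjp(g):
        return (_unbroadcast(g * y.data, x.data.shape),
                _unbroadcast(g * x.data, y.data.shape))

    return Tensor(x.data * y.data, (x, y), vjp)


def div(x, y):
    x, y = _as(x), _as(y)

    def vjp(g):
        return (_unbroadcast(g / y.data, x.data.shape),
                _unbroadcast(-g * x.data / (y.data ** 2), y.data.shape))

    return Tensor(x.data / y.data, (x, y), vjp)


def exp(x):
    x = _as(x)
    out = np.exp(x.data)

    def vjp(g):
        return (g * out,)

    return Tensor(out, (x,), vjp)


def log(x):
    x = _as(x)

    def vjp(g):
        return (g / x.data,)

    return Tensor(np.log(x.data), (x,), vjp)


def tsum(x, axis=None, keepdims=False):
    x = _as(x)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, x.data.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        return (np.broadcast_to(gg, x.data.shape).copy(),)

    return Tensor(x.data.sum(axis=axis, keepdims=keepdims), (x,), vjp)


def matmul(x, y):
    x, y = _as(x), _as(y)

    def vjp(g):
        gx = np.matmul(g, np.swapaxes(y.data, -1, -2))
        gy = np.matmul(np.swapaxes(x.data, -1, -2), g)
        return _unbroadcast(gx, x.data.shape), _unbroadcast(gy, y.data.shape)

    return Tensor(np.matmul(x.data, y.data), (x, y), vjp)


def transpose(x, axes):
    x = _as(x)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (g.transpose(inv),)

    return Tensor(x.data.transpose(axes), (x,), vjp)


def reshape(x, shape):
    x = _as(x)

    def vjp(g):
        return (g.reshape(x.data.shape),)

    return Tensor(x.data.reshape(shape), (x,), vjp)


def _is_fancy(idx):
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, (np.ndarray, list)) for i in items)


def getitem(x, idx):
    x = _as(x)
    fancy = _is_fancy(idx)

    def vjp(g):
        z = np.zeros_like(x.data)
        if fancy:
            np.add.at(z, idx, g)
        else:
            z[idx] += g
        return (z,)

    return Tensor(x.data[idx], (x,), vjp)


def concat(parts, axis):
    parts = [_as(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), vjp)


def stack(parts, axis=0):
    parts = [_as(p) for p in parts]

    def vjp(g):
        return tuple(np.moveaxis(g, axis, 0)[k] for k in range(len(parts)))

    return Tensor(np.stack([p.data for p in parts], axis=axis), tuple(parts), vjp)


def where(mask, x, y):
    """Elementwise select by a constant boolean mask (not differentiated)."""
    mask = np.asarray(mask, dtype=bool)
    x, y = _as(x), _as(y)

    def vjp(g):
        return (_unbroadcast(np.where(mask, g, 0.0), x.data.shape),
                _unbroadcast(np.where(mask, 0.0, g), y.data.shape))

    return Tensor(np.where(mask, x.data, y.data), (x, y), vjp)


def take_cols(x, idx):
    """x[..., idx] for a constant integer index array over the last axis."""
    x = _as(x)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        z = np.zeros_like(x.data)
        np.add.at(z, (Ellipsis, idx), g)
        return (z,)

    return Tensor(x.data[..., idx], (x,), vjp)


def put_cols(x, idx, ncols):
    """Scatter x (..., K) into a (..., ncols) array at column positions idx.

    idx must not contain duplicates; unset columns are zero.
    """
    x = _as(x)
    idx = np.asarray(idx, dtype=np.intp)

    out = np.zeros(x.data.shape[:-1] + (ncols,), dtype=np.float64)
    out[..., idx] = x.data

    def vjp(g):
        return (g[..., idx],)

    return Tensor(out, (x,), vjp)


# -- composite helpers ---------------------------------------------------

def lse(parts):
    """Elementwise log-sum-exp of a list of same-shape tensors."""
    X = stack(parts, 0)
    return lse_axis(X, 0)


def lse_axis(x, axis, keepdims=False):
    x = _as(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    s = tsum(exp(x - Tensor(m)), axis=axis, keepdims=True)
    out = log(s) + Tensor(m)
    if not keepdims:
        out = reshape(out, np.squeeze(out.data, axis=axis).shape)
    return out


def log_softmax(x, axis):
    return _as(x) - lse_axis(x, axis, keepdims=True)


def softmax(x, axis):
    return exp(log_softmax(x, axis))


# -- backward pass -------------------------------------------------------

def _topo(out):
    order, seen, work = [], set(), [(out, False)]
    while work:
        t, done = work.pop()
        if done:
            order.append(t)
            continue
        if id(t) in seen:
            continue
        seen.add(id(t))
        work.append((t, True))
        for p in t.parents:
            if p.requires_grad and id(p) not in seen:
                work.append((p, False))
    return order


def grad(out, wrt, seed=None):
    """Gradients of `out` with respect to each tensor in `wrt`.

    `seed` is the upstream cotangent (defaults to ones, i.e. out must be
    treated as summed if non-scalar).
    """
    if not out.requires_grad:
        return [np.zeros_like(w.data) for w in wrt]
    order = _topo(out)
    grads = {id(out): np.ones_like(out.data) if seed is None else np.asarray(seed, dtype=np.float64)}
    for t in reversed(order):
        g = grads.get(id(t))
        if g is None or t.vjp is None:
            continue
        for p, pg in zip(t.parents, t.vjp(g)):
            if not p.requires_grad:
                continue
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else acc + pg
    return [grads.get(id(w), np.zeros_like(w.data)) for w in wrt]
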