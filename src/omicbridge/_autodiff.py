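"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine covering exactly the operations the generator /
critic networks need.  Every backward rule is itself written with engine
operations, so gradients produced with ``create_graph=True`` can be
differentiated again — the critic's gradient penalty needs this
(second-order) path.

All tensors are float64.  There is no broadcasting beyond what the backward
rules explicitly undo (trailing-dim and size-1 broadcasting, numpy style).
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = []  # list of (Tensor, vjp callable)
        self.requires_grad = bool(requires_grad)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data, parents) -> Tensor:
    """Build an op result, recording parents only when the graph is live."""
    out = Tensor(data)
    if _GRAD_ENABLED:
        live = [(p, vjp) for p, vjp in parents if p.requires_grad]
        if live:
            out.parents = live
            out.requires_grad = True
    return out


# ---------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    # remove extra leading axes
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    # collapse broadcast (size-1) axes
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.shape)),
         (b, lambda g: _unbroadcast(g, b.shape))],
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _result(-a.data, [(a, lambda g: neg(g))])


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data * b.data,
        [(a, lambda g: _unbroadcast(mul(g, b), a.shape)),
         (b, lambda g: _unbroadcast(mul(g, a), b.shape))],
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return _result(
        a.data ** p,
        [(a, lambda g: mul(g, mul(power(a, p - 1.0), p)))],
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(x, w) -> Tensor:
    """x (..., k) @ w (k, m); w must be 2-D."""
    x, w = as_tensor(x), as_tensor(w)
    if w.ndim != 2:
        raise ValueError("matmul right operand must be 2-D")
    k, m = w.shape

    def vjp_x(g):
        return matmul(g, transpose(w))

    def vjp_w(g):
        return matmul(transpose(reshape(x, (-1, k))), reshape(g, (-1, m)))

    return _result(np.matmul(x.data, w.data), [(x, vjp_x), (w, vjp_w)])


def transpose(a) -> Tensor:
    a = as_tensor(a)
    if a.ndim != 2:
        raise ValueError("transpose supports 2-D tensors only")
    return _result(a.data.T.copy(), [(a, lambda g: transpose(g))])


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.shape
    return _result(a.data.reshape(shape).copy(), [(a, lambda g: reshape(g, orig))])


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.shape
    return _result(
        np.broadcast_to(a.data, shape).copy(),
        [(a, lambda g: _unbroadcast(g, orig))],
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    orig = a.shape

    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def vjp(g):
        kd_shape = tuple(1 if i in axes else s for i, s in enumerate(orig))
        return broadcast_to(reshape(g, kd_shape), orig)

    return _result(a.data.sum(axis=axes, keepdims=keepdims), [(a, vjp)])


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.size
    elif isinstance(axis, int):
        count = a.shape[axis]
    else:
        count = 1
        for ax in axis:
            count *= a.shape[ax]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float64)
    return _result(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


def shift_left(a) -> Tensor:
    """y[:, t] = x[:, t+1] along axis 1; last position zero-filled."""
    a = as_tensor(a)
    out = np.zeros_like(a.data)
    out[:, :-1] = a.data[:, 1:]
    return _result(out, [(a, lambda g: shift_right(g))])


def shift_right(a) -> Tensor:
    a = as_tensor(a)
    out = np.zeros_like(a.data)
    out[:, 1:] = a.data[:, :-1]
    return _result(out, [(a, lambda g: shift_left(g))])


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    orig = a.shape
    data = a.data[idx]
    if np.isscalar(data) or data.ndim == 0:
        data = np.asarray(data, dtype=np.float64)
    else:
        data = data.copy()
    return _result(data, [(a, lambda g: scatter(g, idx, orig))])


def scatter(g, idx, shape) -> Tensor:
    g = as_tensor(g)
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return _result(out, [(g, lambda h: getitem(h, idx))])


# ---------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------

def _topo(output: Tensor):
    order, seen, stack = [], set(), [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # children appear after parents


def grad(output: Tensor, inputs, create_graph: bool = False, grad_output=None):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph
    and may be differentiated again.
    """
    if output.size != 1 and grad_output is None:
        raise ValueError("grad requires a scalar output (or explicit grad_output)")
    seed = as_tensor(grad_output) if grad_output is not None \
        else Tensor(np.ones_like(output.data))

    ctx = no_grad() if not create_graph else _nullcontext()
    with ctx:
        grads = {id(output): seed}
        for node in reversed(_topo(output)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            for p, vjp in node.parents:
                contrib = vjp(g)
                prev = grads.get(id(p))
                grads[id(p)] = contrib if prev is None else add(prev, contrib)
            # keep gradients of requested leaves
            for inp in inputs:
                if node is inp:
                    grads[id(node)] = g
        out = []
        for inp in inputs:
            g = grads.get(id(inp))
            out.append(g if g is not None else Tensor(np.zeros_like(inp.data)))
    return out


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
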