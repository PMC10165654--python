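"""Minimal tape-based reverse-mode automatic differentiation on numpy arrays.

Written for the neural-network potential: training on forces needs the
gradient (w.r.t. weights and descriptor parameters) of a loss that itself
contains a gradient (the forces, -dU/dx).  Backward passes are therefore
built from taped operations, so ``grad`` output is differentiable again —
the same trick as ``create_graph=True`` in the large autodiff frameworks,
here for the handful of array primitives the potential actually uses.

Not a general library: broadcasting is supported, dtype is float64, and the
op set is exactly what descriptors + a feed-forward network need.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


class Var:
    """Node in the computation graph; ``v`` is the numpy value."""

    __slots__ = ("v", "parents")

    def __init__(self, v, parents: Tuple = ()):  # parents: ((Var, vjp), ...)
        self.v = np.asarray(v, dtype=np.float64)
        self.parents = parents

    @property
    def shape(self):
        return self.v.shape

    # -- operator sugar ----------------------------------------------------
    def __add__(self, o):
        return add(self, o)

    __radd__ = __add__

    def __sub__(self, o):
        return sub(self, o)

    def __rsub__(self, o):
        return sub(o, self)

    def __mul__(self, o):
        return mul(self, o)

    __rmul__ = __mul__

    def __truediv__(self, o):
        return div(self, o)

    def __rtruediv__(self, o):
        return div(o, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, o):
        return matmul(self, o)

    def __repr__(self):
        return f"Var(shape={self.v.shape})"


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def _sum_to(g: Var, shape) -> Var:
    """Reduce a cotangent to ``shape`` by summing broadcast axes."""
    if g.shape == tuple(shape):
        return g
    v = g
    # leading added axes
    while len(v.shape) > len(shape):
        v = sum_axis(v, 0)
    for ax, (sg, st) in enumerate(zip(v.shape, shape)):
        if st == 1 and sg != 1:
            v = sum_axis(v, ax, keepdims=True)
    return reshape(v, shape)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(a.v + b.v, ((a, lambda g: _sum_to(g, a.shape)),
                           (b, lambda g: _sum_to(g, b.shape))))


def sub(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(a.v - b.v, ((a, lambda g: _sum_to(g, a.shape)),
                           (b, lambda g: _sum_to(neg(g), b.shape))))


def mul(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(a.v * b.v, ((a, lambda g: _sum_to(mul(g, b), a.shape)),
                           (b, lambda g: _sum_to(mul(g, a), b.shape))))


def div(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return mul(a, power(b, -1.0))


def neg(a) -> Var:
    a = as_var(a)
    return Var(-a.v, ((a, lambda g: neg(g)),))


def power(a, c: float) -> Var:
    a = as_var(a)
    c = float(c)
    return Var(a.v ** c,
               ((a, lambda g: mul(g, mul(c, power(a, c - 1.0)))),))


def vexp(a) -> Var:
    a = as_var(a)
    out = Var(np.exp(a.v))
    out.parents = ((a, lambda g: mul(g, vexp(a))),)
    return out


def vtanh(a) -> Var:
    a = as_var(a)
    return Var(np.tanh(a.v),
               ((a, lambda g: mul(g, sub(1.0, power(vtanh(a), 2.0)))),))


def vcos(a) -> Var:
    a = as_var(a)
    return Var(np.cos(a.v), ((a, lambda g: neg(mul(g, vsin(a)))),))


def vsin(a) -> Var:
    a = as_var(a)
    return Var(np.sin(a.v), ((a, lambda g: mul(g, vcos(a))),))


def matmul(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(a.v @ b.v,
               ((a, lambda g: matmul(g, transpose(b))),
                (b, lambda g: matmul(transpose(a), g))))


def transpose(a) -> Var:
    a = as_var(a)
    return Var(a.v.T, ((a, lambda g: transpose(g)),))


def reshape(a, shape) -> Var:
    a = as_var(a)
    shape = tuple(shape)
    old = a.shape
    return Var(a.v.reshape(shape), ((a, lambda g: reshape(g, old)),))


def sum_all(a) -> Var:
    a = as_var(a)
    shp = a.shape
    return Var(np.sum(a.v), ((a, lambda g: broadcast_to(g, shp)),))


def sum_axis(a, axis: int, keepdims: bool = False) -> Var:
    a = as_var(a)
    shp = a.shape

    def back(g):
        if not keepdims:
            kshape = list(shp)
            kshape[axis] = 1
            g = reshape(g, kshape)
        return broadcast_to(g, shp)

    return Var(np.sum(a.v, axis=axis, keepdims=keepdims), ((a, back),))


def broadcast_to(a, shape) -> Var:
    a = as_var(a)
    shape = tuple(shape)
    old = a.shape
    return Var(np.broadcast_to(a.v, shape).copy(),
               ((a, lambda g: _sum_to(g, old)),))


def gather(a, idx: np.ndarray) -> Var:
    """Rows a[idx] along axis 0."""
    a = as_var(a)
    idx = np.asarray(idx)
    n = a.shape[0]
    return Var(a.v[idx], ((a, lambda g: scatter_add(g, idx, n)),))


def scatter_add(src, idx: np.ndarray, n: int) -> Var:
    """out[k] = sum of src rows with idx == k; out has n rows."""
    src = as_var(src)
    idx = np.asarray(idx)
    out = np.zeros((n,) + src.shape[1:], dtype=np.float64)
    np.add.at(out, idx, src.v)
    return Var(out, ((src, lambda g: gather(g, idx)),))


def where_const(mask: np.ndarray, a) -> Var:
    """a masked by a constant boolean array (zeros elsewhere)."""
    a = as_var(a)
    m = np.asarray(mask, dtype=np.float64)
    return mul(a, Var(m))


def column_stack(cols: Sequence[Var]) -> Var:
    """Stack 1-D Vars of length N into an N x k matrix."""
    cols = [as_var(c) for c in cols]
    n = cols[0].shape[0]
    k = len(cols)
    out = reshape(cols[0], (n, 1))
    for c in cols[1:]:
        out = concat_cols(out, reshape(c, (n, 1)))
    return out


def concat_cols(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    ka = a.shape[1]

    def back_a(g):
        return slice_cols(g, 0, ka)

    def back_b(g):
        return slice_cols(g, ka, g.shape[1])

    return Var(np.concatenate([a.v, b.v], axis=1), ((a, back_a), (b, back_b)))


def slice_cols(a, lo: int, hi: int) -> Var:
    a = as_var(a)
    shp = a.shape

    def back(g):
        left = Var(np.zeros((shp[0], lo)))
        right = Var(np.zeros((shp[0], shp[1] - hi)))
        out = g
        if lo:
            out = concat_cols(left, out)
        if hi < shp[1]:
            out = concat_cols(out, right)
        return out

    return Var(a.v[:, lo:hi], ((a, back),))


# ---------------------------------------------------------------------------
# Gradient
# ---------------------------------------------------------------------------


def _topo(out: Var) -> List[Var]:
    order: List[Var] = []
    seen = set()
    stack = [(out, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            stack.append((p, False))
    return order


def grad(out: Var, wrts: Sequence[Var],
         cotangent: Optional[Var] = None) -> List[Var]:
    """Cotangents of ``out`` w.r.t. each Var in ``wrts``.

    The returned Vars carry their own tape, so they can be differentiated
    again (second-order / gradient-of-gradient).  Vars not reachable from
    ``out`` get zero gradients.
    """
    order = _topo(out)
    cot = {id(out): cotangent if cotangent is not None
           else Var(np.ones_like(out.v))}
    for node in reversed(order):
        g = cot.get(id(node))
        if g is None:
            continue
        for parent, vjp in node.parents:
            contrib = vjp(g)
            prev = cot.get(id(parent))
            cot[id(parent)] = contrib if prev is None else add(prev, contrib)
    return [cot.get(id(w), Var(np.zeros_like(w.v))) for w in wrts]
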