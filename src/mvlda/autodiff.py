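"""Minimal reverse-mode automatic differentiation over dense numpy arrays.

The model is a small, full-batch graph network trained on dense matrices, so
a tape-based engine with a dozen primitives covers everything the encoder,
decoder and loss require: matrix products, broadcast addition, elementwise
nonlinearities, row/column slicing, concatenation, masked softmax and
squared-error reductions.  Gradients are exact (validated against central
finite differences in the test suite).

Only :class:`Tensor` and the free functions below are public.  A ``Tensor``
wraps a float64 ndarray; operations build a DAG and :meth:`Tensor.backward`
accumulates gradients into every node with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "relu",
    "tanh",
    "concat_cols",
    "concat_rows",
    "slice_rows",
    "masked_softmax",
    "sum_squares",
    "masked_sum_squares",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that numpy broadcasting expanded, back to `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad: bool = False, parents=(), vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = parents
        self._vjp = vjp  # callable(grad_out) -> tuple of grads for parents

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Accumulate d(self)/d(leaf) into every reachable grad-requiring leaf.

        `self` must be scalar-valued (a loss).
        """
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, scale(_as_tensor(other), -1.0))

    def __mul__(self, other):
        if np.isscalar(other):
            return scale(self, float(other))
        return multiply(self, _as_tensor(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    @property
    def T(self):
        return transpose(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True)


# -- primitives ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.value + b.value

    def vjp(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)

    return Tensor(out, parents=(a, b), vjp=vjp)


def multiply(a: Tensor, b: Tensor) -> Tensor:
    out = a.value * b.value

    def vjp(g):
        return (_unbroadcast(g * b.value, a.value.shape),
                _unbroadcast(g * a.value, b.value.shape))

    return Tensor(out, parents=(a, b), vjp=vjp)


def scale(a: Tensor, s: float) -> Tensor:
    def vjp(g):
        return (g * s,)

    return Tensor(a.value * s, parents=(a,), vjp=vjp)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value @ b.value

    def vjp(g):
        return g @ b.value.T, a.value.T @ g

    return Tensor(out, parents=(a, b), vjp=vjp)


def transpose(a: Tensor) -> Tensor:
    def vjp(g):
        return (g.T,)

    return Tensor(a.value.T, parents=(a,), vjp=vjp)


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0

    def vjp(g):
        return (g * mask,)

    return Tensor(a.value * mask, parents=(a,), vjp=vjp)


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.value)

    def vjp(g):
        return (g * (1.0 - out * out),)

    return Tensor(out, parents=(a,), vjp=vjp)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    na = a.value.shape[1]

    def vjp(g):
        return g[:, :na], g[:, na:]

    return Tensor(np.concatenate([a.value, b.value], axis=1),
                  parents=(a, b), vjp=vjp)


def concat_rows(a: Tensor, b: Tensor) -> Tensor:
    na = a.value.shape[0]

    def vjp(g):
        return g[:na], g[na:]

    return Tensor(np.concatenate([a.value, b.value], axis=0),
                  parents=(a, b), vjp=vjp)


def slice_rows(a: Tensor, start: int, stop: int) -> Tensor:
    def vjp(g):
        full = np.zeros_like(a.value)
        full[start:stop] = g
        return (full,)

    return Tensor(a.value[start:stop], parents=(a,), vjp=vjp)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to entries where ``mask`` is nonzero.

    Every row must have at least one unmasked entry (graph self-loops
    guarantee this).  The row max over the support is subtracted before
    exponentiation; by shift invariance of softmax this does not change the
    value or the gradient.
    """
    m = mask.astype(bool)
    if not m.any(axis=1).all():
        raise ValueError("masked_softmax: a row has an empty support")
    shifted = np.where(m, scores.value, -np.inf)
    shifted = shifted - shifted.max(axis=1, keepdims=True)
    ex = np.where(m, np.exp(shifted), 0.0)
    out = ex / ex.sum(axis=1, keepdims=True)

    def vjp(g):
        # d softmax: P * (g - sum(g*P)) restricted to the support
        inner = (g * out).sum(axis=1, keepdims=True)
        return (out * (g - inner),)

    return Tensor(out, parents=(scores,), vjp=vjp)


def sum_squares(a: Tensor) -> Tensor:
    def vjp(g):
        return (2.0 * g * a.value,)

    return Tensor(np.sum(a.value * a.value), parents=(a,), vjp=vjp)


def masked_sum_squares(a: Tensor, mask: np.ndarray) -> Tensor:
    """||mask ⊙ a||_F² with a 0/1 mask held constant."""

    def vjp(g):
        return (2.0 * g * mask * a.value,)

    return Tensor(np.sum(mask * a.value * a.value), parents=(a,), vjp=vjp)
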