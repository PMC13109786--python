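"""A small reverse-mode automatic-differentiation core on numpy arrays.

The interaction model needs gradients in two places: parameter gradients for
training and input-feature gradients for saliency mapping. Both come from
the same machinery here: a :class:`Tensor` wraps an ndarray and records the
operations applied to it; :meth:`Tensor.backward` propagates cotangents
through the recorded graph in reverse topological order.

Only the operations the encoder actually uses are implemented, including two
graph-specific primitives: ``gather`` (row lookup whose adjoint is a sparse
scatter-add) and ``segment_softmax`` (softmax over contiguous, pre-sorted
index segments — the per-neighborhood attention normalization). Gradient
correctness is pinned by central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "div", "matmul", "gather", "sparse_matmul",
    "segment_softmax", "leaky_relu", "elu", "sigmoid", "exp", "log", "sqrt",
    "abs_", "sum_", "mean_", "reshape", "concat", "layer_norm", "dropout",
    "bce_with_logits",
]


class Tensor:
    """ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None
        self._grad_shared = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (many layers/batches)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            # adopt the buffer without copying; it may be aliased elsewhere
            # (or be a read-only broadcast view), so it is never mutated in
            # place while the _grad_shared flag is set
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None
        self._grad_shared = False

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, Tensor(np.array(-1.0, dtype=self.data.dtype)))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- elementwise arithmetic ---------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return Tensor._wrap(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(-_unbroadcast(g, b.shape))

    return Tensor._wrap(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return Tensor._wrap(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        a._accum(_unbroadcast(g / b.data, a.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return Tensor._wrap(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return Tensor._wrap(out_data, (a, b), backward)


# -- nonlinearities -----------------------------------------------------------

#: when not None, leaky_relu appends the sign pattern of its input here;
#: used by finite-difference checks to detect kink crossings
KINK_TRACE: list | None = None


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    if KINK_TRACE is not None:
        KINK_TRACE.append(pos.copy())
    out_data = np.where(pos, x.data, slope * x.data)

    def backward(g):
        x._accum(np.where(pos, g, slope * g))

    return Tensor._wrap(out_data, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    expm1 = np.expm1(np.minimum(x.data, 0.0))
    out_data = np.where(pos, x.data, alpha * expm1)

    def backward(g):
        x._accum(np.where(pos, g, g * alpha * (expm1 + 1.0)))

    return Tensor._wrap(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._wrap(out_data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g):
        x._accum(g * out_data)

    return Tensor._wrap(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward(g):
        x._accum(g / x.data)

    return Tensor._wrap(out_data, (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def backward(g):
        x._accum(g * 0.5 / out_data)

    return Tensor._wrap(out_data, (x,), backward)


def abs_(x: Tensor) -> Tensor:
    sign = np.sign(x.data)
    out_data = np.abs(x.data)

    def backward(g):
        x._accum(g * sign)

    return Tensor._wrap(out_data, (x,), backward)


# -- reductions / shape -------------------------------------------------------

def sum_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(np.broadcast_to(g, x.shape))

    return Tensor._wrap(out_data, (x,), backward)


def mean_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    n = x.data.size if axis is None else x.shape[axis]
    return sum_(x, axis=axis, keepdims=keepdims) * Tensor(
        np.array(1.0 / n, dtype=x.dtype))


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accum(g.reshape(x.shape))

    return Tensor._wrap(out_data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._wrap(out_data, tuple(tensors), backward)


# -- graph primitives ---------------------------------------------------------

def gather(x: Tensor, idx: np.ndarray, scatter=None) -> Tensor:
    """Row lookup ``out[e] = x[idx[e]]``.

    ``scatter`` may supply a precomputed sparse (n_rows x n_out) matrix with
    ``scatter[i, e] = 1`` iff ``idx[e] == i``; the adjoint is then a sparse
    matmul instead of a slow ``np.add.at``.
    """
    out_data = x.data[idx]

    def backward(g):
        if scatter is not None:
            x._accum(scatter @ g)
        else:
            acc = np.zeros(x.shape, dtype=g.dtype)
            np.add.at(acc, idx, g)
            x._accum(acc)

    return Tensor._wrap(out_data, (x,), backward)


def sparse_matmul(S, x: Tensor) -> Tensor:
    """``S @ x`` for a constant scipy sparse matrix ``S``."""
    out_data = S @ x.data

    def backward(g):
        x._accum(S.T @ g)

    return Tensor._wrap(out_data, (x,), backward)


def segment_softmax(scores: Tensor, starts: np.ndarray,
                    seg_of: np.ndarray) -> Tensor:
    """Softmax over contiguous row segments.

    ``scores`` is (E, H) with rows already sorted so that segment k occupies
    rows ``starts[k]:starts[k+1]``; ``seg_of[e]`` is the segment of row e.
    Each column (attention head) is normalized independently per segment.
    """
    z = scores.data
    seg_max = np.maximum.reduceat(z, starts[:-1], axis=0)
    ez = np.exp(z - seg_max[seg_of])
    seg_sum = np.add.reduceat(ez, starts[:-1], axis=0)
    out_data = ez / seg_sum[seg_of]

    def backward(g):
        dot = np.add.reduceat(out_data * g, starts[:-1], axis=0)
        scores._accum(out_data * (g - dot[seg_of]))

    return Tensor._wrap(out_data, (scores,), backward)


# -- normalization / regularization ------------------------------------------

def layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalization with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data
    n = x.shape[-1]

    def backward(g):
        bias._accum(_unbroadcast(g, bias.shape))
        gain._accum(_unbroadcast(g * xhat, gain.shape))
        gh = g * gain.data
        # standard layernorm backward
        dx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
        x._accum(dx)

    return Tensor._wrap(out_data, (x, gain, bias), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    out_data = x.data * mask

    def backward(g):
        x._accum(g * mask)

    return Tensor._wrap(out_data, (x,), backward)


# -- losses -------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype).reshape(z.shape)
    # log(1 + e^z) computed stably
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array((softplus - y * z).mean(), dtype=z.dtype)
    p = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        logits._accum(g * (p - y) / z.size)

    return Tensor._wrap(out_data, (logits,), backward)
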