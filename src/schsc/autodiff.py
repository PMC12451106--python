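"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective mixes a contrastive softmax over a fused similarity
matrix with a zero-inflated negative binomial likelihood, so the engine only
needs a small closed set of primitives: affine maps, elementwise
exp/log/sigmoid/ELU, ``lgamma`` (whose gradient is the digamma function),
reductions, concatenation and clamping.  Everything is float64 and
single-threaded, which keeps repeated runs bitwise reproducible.

Gradient correctness of every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction -------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, parents=parents, backward=backward)
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g, out):
            if self.requires_grad:
                self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self) -> "Tensor":
        val = np.exp(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * val)

        return self._make(val, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self) -> "Tensor":
        # numerically stable in both tails
        val = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, 0, None))),
            np.exp(np.clip(self.data, None, 0))
            / (1.0 + np.exp(np.clip(self.data, None, 0))),
        )

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * val * (1.0 - val))

        return self._make(val, (self,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        val = np.where(self.data > 0, self.data, neg)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, neg + alpha))

        return self._make(val, (self,), backward)

    def lgamma(self) -> "Tensor":
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * digamma(self.data))

        return self._make(gammaln(self.data), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is zero outside [lo, hi] (as torch.clamp)."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backprop --------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor(data, parents=tuple(tensors), backward=backward)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
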