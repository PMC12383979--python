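"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (tens of thousands of parameters, clips of
a few thousand samples), so a compact tape-based engine is sufficient: a
:class:`Tensor` wraps an ``ndarray``, records its parents and a backward
closure, and :meth:`Tensor.backward` walks the tape in reverse topological
order.  Gradients of every primitive are verified against central finite
differences in the test suite.

Supported primitives: broadcasting add/sub/mul, two-operand ``einsum``,
``relu``, ``sigmoid``, ``softplus``, row ``softmax``, ``reshape``,
``transpose``, slicing, zero-padding of the trailing axis, ``sum``/``mean``.
Everything else in the package (attention, graph convolution, dilated
convolution, the classifier head) is composed from these.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
            if self.grad.shape != self.data.shape:  # broadcast-safe seed
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = _bw
        return out

    def pad_last(self, before: int, after: int) -> "Tensor":
        """Zero-pad the trailing (time) axis."""
        width = [(0, 0)] * (self.ndim - 1) + [(before, after)]
        out = Tensor(np.pad(self.data, width), self.requires_grad, (self,))
        T = self.shape[-1]

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g[..., before:before + T])

        out._backward = _bw
        return out

    # ---------------------------------------------------------- contractions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        shape = self.shape

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- nonlinear
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor(s, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def softplus(self) -> "Tensor":
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 * (1.0 + np.tanh(0.5 * self.data)))

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        out._backward = _bw
        return out


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with gradients.

    Constraint: no repeated index within a single operand, and every index of
    each operand must appear in the output or the other operand (so the
    gradient is itself an einsum with permuted subscripts).
    """
    lhs, out_sub = spec.replace(" ", "").split("->")
    sub_a, sub_b = lhs.split(",")
    for sub, other in ((sub_a, sub_b), (sub_b, sub_a)):
        if len(set(sub)) != len(sub):
            raise ValueError(f"repeated index in operand subscript {sub!r}")
        if not set(sub) <= set(out_sub) | set(other):
            raise ValueError(f"index of {sub!r} absent from output and other operand")
    out = Tensor(np.einsum(spec, a.data, b.data, optimize=True),
                 a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out_sub},{sub_b}->{sub_a}", g, b.data, optimize=True))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out_sub},{sub_a}->{sub_b}", g, a.data, optimize=True))

    out._backward = _bw
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None, fan_out: int | None = None) -> np.ndarray:
    """Fan-based uniform initialization."""
    if fan_in is None:
        fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    if fan_out is None:
        fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a list of :class:`Tensor` parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
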