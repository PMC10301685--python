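"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the drug-response architectures need:
affine maps, masked affine maps (sparse layers wired by binary membership
matrices), elementwise nonlinearities, softmax attention, concatenation and
reductions — plus an Adam optimizer. Gradients for masked layers are masked
by construction (the forward pass multiplies the weight by the mask), so
off-mask weights receive zero gradient and stay exactly zero.

The engine is deliberately small: float64 throughout, CPU only, no
broadcasting beyond what the layers below use, and a topological-order
backward pass over a dynamically recorded tape.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "relu", "tanh", "sigmoid", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _node(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = parents
            out._backward = backward
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_holder: list[Tensor] = []

        def backward():
            g = out_holder[0].grad
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out = Tensor._node(self.data + other.data, (self, other), backward)
        out_holder.append(out)
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_holder: list[Tensor] = []

        def backward():
            g = out_holder[0].grad
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out = Tensor._node(self.data * other.data, (self, other), backward)
        out_holder.append(out)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * Tensor(-1.0))

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out_holder: list[Tensor] = []

        def backward():
            g = out_holder[0].grad
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out = Tensor._node(self.data @ other.data, (self, other), backward)
        out_holder.append(out)
        return out

    def __matmul__(self, other):
        return self.matmul(other)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_holder: list[Tensor] = []

        def backward():
            g = out_holder[0].grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out = Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)
        out_holder.append(out)
        return out

    def mean(self) -> "Tensor":
        return self.sum() * Tensor(1.0 / self.data.size)

    def reshape(self, *shape) -> "Tensor":
        out_holder: list[Tensor] = []

        def backward():
            self._accum(out_holder[0].grad.reshape(self.data.shape))

        out = Tensor._node(self.data.reshape(*shape), (self,), backward)
        out_holder.append(out)
        return out

    def __pow__(self, p: float) -> "Tensor":
        out_holder: list[Tensor] = []

        def backward():
            self._accum(out_holder[0].grad * p * self.data ** (p - 1))

        out = Tensor._node(self.data**p, (self,), backward)
        out_holder.append(out)
        return out

    # -- backward driver ----------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the recorded tape."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


class Parameter(Tensor):
    """A trainable tensor, optionally constrained by a binary mask."""

    __slots__ = ("mask",)

    def __init__(self, data, mask: np.ndarray | None = None):
        data = np.asarray(data, dtype=np.float64)
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float64)
            if mask.shape != data.shape:
                raise ValueError("mask shape must match parameter shape")
            data = data * mask
        super().__init__(data, requires_grad=True)
        self.mask = mask


def relu(x: Tensor) -> Tensor:
    out_holder: list[Tensor] = []

    def backward():
        x._accum(out_holder[0].grad * (x.data > 0))

    out = Tensor._node(np.maximum(x.data, 0.0), (x,), backward)
    out_holder.append(out)
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out_holder: list[Tensor] = []

    def backward():
        x._accum(out_holder[0].grad * (1.0 - t * t))

    out = Tensor._node(t, (x,), backward)
    out_holder.append(out)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_holder: list[Tensor] = []

    def backward():
        x._accum(out_holder[0].grad * s * (1.0 - s))

    out = Tensor._node(s, (x,), backward)
    out_holder.append(out)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out_holder: list[Tensor] = []

    def backward():
        g = out_holder[0].grad
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out = Tensor._node(s, (x,), backward)
    out_holder.append(out)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_holder: list[Tensor] = []

    def backward():
        g = out_holder[0].grad
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, stop)
                t._accum(g[tuple(idx)])

    out = Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
    out_holder.append(out)
    return out


class Adam:
    """Adam optimizer with per-step mask re-application.

    Masked parameters are re-multiplied by their mask after every update, so
    the invariant "off-mask weight == 0" holds exactly at all times (the
    gradient there is already zero; re-masking guards against numerical dust
    from the moment estimates).
    """

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.mask is not None:
                p.data *= p.mask
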