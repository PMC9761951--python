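"""Minimal reverse-mode automatic differentiation on numpy arrays.

The joint model trains several coupled sub-networks (per-view feature
nets, pairwise correlation projections, a graph-convolutional trunk and
a Cox head) against a single partial-likelihood loss, so we need exact
reverse-mode gradients through arbitrary compositions of affine maps,
elementwise nonlinearities, outer products and log-sum-exp terms.  This
module provides a small tape-based ``Tensor`` wrapping ``numpy.float64``
arrays, the handful of differentiable operations the model composes,
and an Adam optimizer.  Gradient correctness is enforced by the test
suite via central finite differences.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "relu", "concat_rows", "logsumexp_rows", "Adam", "glorot"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A float64 array node on an implicit backward tape.

    Parameters with ``requires_grad=True`` accumulate ``.grad`` after
    ``backward()`` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_accumulate")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    # -- autodiff plumbing ----------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # gather the reachable graph and count consumers of every node, then
        # propagate from the loss, releasing a node only once every consumer
        # has sent its gradient (a plain DFS postorder mis-orders diamonds)
        nodes: list[Tensor] = []
        seen: set[int] = set()
        stack: list[Tensor] = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            nodes.append(node)
            stack.extend(node._parents)
        pending: dict[int, int] = {id(n): 0 for n in nodes}
        for n in nodes:
            for p in n._parents:
                pending[id(p)] += 1
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        ready: list[Tensor] = [self]
        while ready:
            node = ready.pop()
            g = grads.pop(id(node), None)
            if g is not None:
                if node.requires_grad and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                if node._backward is not None:
                    node._accumulate = grads
                    node._backward(g)
                    del node._accumulate
            released: set[int] = set()
            for p in node._parents:
                pending[id(p)] -= 1
                if pending[id(p)] == 0 and id(p) not in released:
                    released.add(id(p))
                    ready.append(p)

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        grads = self._accumulate  # type: ignore[attr-defined]
        key = id(parent)
        if key in grads:
            grads[key] = grads[key] + g
        else:
            grads[key] = g

    # -- operations -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g, self.data.shape))
            out._send(other, _unbroadcast(g, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, -g)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g * other.data, self.data.shape))
            out._send(other, _unbroadcast(g * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            out._send(self, g @ other.data.T)
            out._send(other, self.data.T @ g)

        out = self._make(out_data, (self, other), backward)
        return out

    @property
    def T(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, g.T)

        out = self._make(self.data.T, (self,), backward)
        return out

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g: np.ndarray) -> None:
            out._send(self, g.reshape(old))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    def sum(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, np.broadcast_to(g, self.data.shape).copy())

        out = self._make(self.data.sum(), (self,), backward)
        return out

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, g / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def take(self, idx) -> "Tensor":
        """Integer-array indexing along the first axis."""
        idx = np.asarray(idx)

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            out._send(self, full)

        out = self._make(self.data[idx], (self,), backward)
        return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        out._send(x, g * mask)

    out = x._make(np.where(mask, x.data, 0.0), (x,), backward)
    return out


def concat_rows(parts: Sequence[Tensor]) -> Tensor:
    """Stack 2-D tensors vertically (along axis 0)."""
    datas = [p.data for p in parts]
    splits = np.cumsum([d.shape[0] for d in datas])[:-1]
    out_data = np.concatenate(datas, axis=0)
    anchor = parts[0]

    def backward(g: np.ndarray) -> None:
        for p, gp in zip(parts, np.split(g, splits, axis=0)):
            out._send(p, gp)

    out = anchor._make(out_data, tuple(parts), backward)
    return out


def logsumexp_rows(riskmat: np.ndarray, phi: Tensor) -> Tensor:
    """Stable ``log(R @ exp(phi))`` for a constant 0/1 risk-set matrix R.

    Each row of ``riskmat`` selects a risk set; the max-shift constant is
    detached, which leaves the gradient (a row-wise softmax) exact.
    """
    shift = float(phi.data.max())
    e = (phi + (-shift)).exp()
    summed_data = riskmat @ e.data

    def backward(g: np.ndarray) -> None:
        e_out._send(e, riskmat.T @ g)

    e_out = phi._make(summed_data, (e,), backward)
    return e_out.log() + shift


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    """Uniform Glorot initialization for a (fan_out, fan_in) weight matrix."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
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
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
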