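"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the fusion network needs: broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions, reshape/concat/
slicing, stable softmax/log-sum-exp, and a strided 2-D convolution (im2col).
Gradients are accumulated by topological-order backpropagation, with
broadcast axes summed out.

This is deliberately tiny and CPU-only; parameters are plain ``Tensor``
objects with ``requires_grad=True`` collected in dicts, optimised by
:class:`Adam`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv2d", "Adam", "glorot", "zeros"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # beat numpy's operators

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(p for p in _parents if p.requires_grad)
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if np.ndim(g) else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))
        out._backward = backward
        return out

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy()
                            if np.ndim(g) else np.full(self.shape, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = backward
        return out

    # -- stable compositions ---------------------------------------------
    def softmax(self, axis=-1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = (self - Tensor(m)).exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            return shifted.reshape(tuple(s for i, s in enumerate(self.shape)
                                         if i != (axis % self.ndim)))
        return shifted


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(part)
    out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, via im2col + matmul.

    ``x``: (N, C, H, W); ``weight``: (F, C, kh, kw); output (N, F, OH, OW).
    """
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    N, C, H, W = xd.shape
    F, _, kh, kw = weight.shape
    OH = (H - kh) // stride + 1
    OW = (W - kw) // stride + 1
    s0, s1, s2, s3 = xd.strides
    view = np.lib.stride_tricks.as_strided(
        xd, shape=(N, C, kh, kw, OH, OW),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride))
    cols = view.reshape(N, C * kh * kw, OH * OW)
    wmat = weight.data.reshape(F, C * kh * kw)
    out_data = np.einsum("fk,nkp->nfp", wmat, cols).reshape(N, F, OH, OW)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, F, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, _parents=parents)

    def backward(g):
        gflat = g.reshape(N, F, OH * OW)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("nfp,nkp->fk", gflat, cols)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("fk,nfp->nkp", wmat, gflat)
            gcols = gcols.reshape(N, C, kh, kw, OH, OW)
            gx = np.zeros((N, C, H, W))
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + stride * OH:stride,
                       j:j + stride * OW:stride] += gcols[:, :, i, j]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# parameter initialisation and optimisation

def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    """Glorot/Xavier-uniform initialised parameter tensor."""
    fan_in = shape[-2] if len(shape) >= 2 else shape[0]
    fan_out = shape[-1]
    if len(shape) == 4:  # conv: (F, C, kh, kw)
        rf = shape[2] * shape[3]
        fan_in, fan_out = shape[1] * rf, shape[0] * rf
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
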