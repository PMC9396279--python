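"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run engine: every operation on :class:`Tensor` records its
parents and a backward closure; :meth:`Tensor.backward` runs a topological
sweep accumulating gradients into ``.grad``.  Only the operations needed by
the synthesis networks are provided (elementwise arithmetic, matmul,
reductions, shape ops, 2-D convolution / pooling / nearest upsampling and the
usual activations).  Everything is float64; graphs are built only along paths
that can reach a parameter, so inference allocates no closures.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float64


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward_fn):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    def _accum(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bwd(g, a=self, e=exponent):
            a._accum(g * e * a.data ** (e - 1))

        return Tensor._result(out_data, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._result(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, ax=axis, kd=keepdims):
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not kd:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._result(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_spatial(self) -> "Tensor":
        """Global max over the trailing two axes (keepdims); used by attention pooling."""
        out_data = self.data.max(axis=(-2, -1), keepdims=True)

        def bwd(g, a=self, od=out_data):
            mask = (a.data == od).astype(DTYPE)
            mask /= np.maximum(mask.sum(axis=(-2, -1), keepdims=True), 1.0)
            a._accum(g * mask)

        return Tensor._result(out_data, (self,), bwd)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g, a=self, s=orig):
            a._accum(g.reshape(s))

        return Tensor._result(out_data, (self,), bwd)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g, a=self, inv=inv):
            a._accum(g.transpose(inv))

        return Tensor._result(out_data, (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(out_data, (self,), bwd)

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g, a=self, od=out_data):
            a._accum(g * od)

        return Tensor._result(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd(g, a=self):
            a._accum(g / a.data)

        return Tensor._result(out_data, (self,), bwd)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bwd(g, a=self, od=out_data):
            a._accum(g * 0.5 / od)

        return Tensor._result(out_data, (self,), bwd)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)

        def bwd(g, a=self):
            a._accum(g * np.sign(a.data))

        return Tensor._result(out_data, (self,), bwd)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bwd(g, a=self):
            a._accum(g * (a.data > 0))

        return Tensor._result(out_data, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out_data = np.where(self.data > 0, self.data, slope * self.data)

        def bwd(g, a=self, s=slope):
            a._accum(g * np.where(a.data > 0, 1.0, s))

        return Tensor._result(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        e = np.exp(-np.abs(self.data))          # never overflows
        out_data = np.where(self.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

        def bwd(g, a=self, od=out_data):
            a._accum(g * od * (1.0 - od))

        return Tensor._result(out_data, (self,), bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g, a=self, od=out_data):
            a._accum(g * (1.0 - od ** 2))

        return Tensor._result(out_data, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient is split equally."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.maximum(a.data, b.data)

    def bwd(g, a=a, b=b):
        ga = np.where(a.data > b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))
        a._accum(_unbroadcast(g * ga, a.data.shape))
        b._accum(_unbroadcast(g * (1.0 - ga), b.data.shape))

    return Tensor._result(out_data, (a, b), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, off=offsets, ax=axis):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            sl = [slice(None)] * g.ndim
            sl[ax] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), bwd)


# -- 2-D convolution and resampling primitives (NCHW layout) -----------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), w (F,C,kh,kw), b (F,)."""
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    xp = x.data if padding == 0 else np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, C * kh * kw)
    out_data = (cols @ wmat.T).reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g, x=x, w=w, b=b, cols=cols, stride=stride, padding=padding,
            dims=(N, C, H, W, F, kh, kw, Ho, Wo, Hp, Wp)):
        N, C, H, W, F, kh, kw, Ho, Wo, Hp, Wp = dims
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, F)
        if w.requires_grad:
            gw = (gmat.T @ cols).reshape(F, C, kh, kw)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # one BLAS matmul back to column space, then scatter per kernel tap
            gcols = (gmat @ w.data.reshape(F, C * kh * kw)).reshape(
                N, Ho, Wo, C, kh, kw)
            gxp = np.zeros((N, C, Hp, Wp), dtype=DTYPE)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] \
                        += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:Hp - padding, padding:Wp - padding]
            x._accum(gxp)

    return Tensor._result(out_data, parents, bwd)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k max pooling; spatial dims must divide k."""
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"max_pool2d: spatial dims ({H},{W}) not divisible by {k}")
    blocks = x.data.reshape(N, C, H // k, k, W // k, k)
    out_data = blocks.max(axis=(3, 5))

    def bwd(g, x=x, k=k, od=out_data):
        N, C, H, W = x.data.shape
        blocks = x.data.reshape(N, C, H // k, k, W // k, k)
        mask = (blocks == od[:, :, :, None, :, None]).astype(DTYPE)
        mask /= np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1.0)
        gx = (mask * g[:, :, :, None, :, None]).reshape(N, C, H, W)
        x._accum(gx)

    return Tensor._result(out_data, (x,), bwd)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims ({H},{W}) not divisible by {k}")
    out_data = x.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def bwd(g, x=x, k=k):
        N, C, H, W = x.data.shape
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gx)

    return Tensor._result(out_data, (x,), bwd)


def upsample_nearest2d(x: Tensor, k: int = 2) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)

    def bwd(g, x=x, k=k):
        N, C, H, W = x.data.shape
        gx = g.reshape(N, C, H, k, W, k).sum(axis=(3, 5))
        x._accum(gx)

    return Tensor._result(out_data, (x,), bwd)
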