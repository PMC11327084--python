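"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the segmentation network needs:
elementwise arithmetic with broadcasting, reductions, matmul (batched),
2-D convolution (im2col), strided transposed convolution, softmax, and the
usual pointwise nonlinearities.  Gradients for the convolution operators are
hand-written and covered by numerical gradient checks in the test suite.

All tensors are float32 by default; the graph is a tape of ``Tensor`` nodes
freed after ``backward``.
"""

from __future__ import annotations

import contextlib

import numpy as np

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # release the tape as we go
                node._backward = None
                node._parents = ()

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._node(self.data**p, (self,), backward)

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(DTYPE))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).astype(DTYPE))

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._node(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor._node(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        return Tensor._node(e, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- composite / structural ops ------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._node(np.matmul(a.data, b.data), (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._node(s, (x,), backward)


def conv2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding."""
    B, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin_w}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (B, Cin, Ho, Wo, kh, kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, Cin * kh * kw
    )
    wmat = w.data.reshape(Cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Cout)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.shape))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, Ho, Wo, Cin, kh, kw)
            gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # (B,Cin,Ho,Wo,kh,kw)
            gxp = np.zeros((B, Cin, Hp, Wp), dtype=DTYPE)
            for ki in range(kh):
                for kj in range(kw):
                    gxp[
                        :, :, ki : ki + stride * Ho : stride, kj : kj + stride * Wo : stride
                    ] += gcols[:, :, :, :, ki, kj]
            if padding:
                gxp = gxp[:, :, padding : padding + H, padding : padding + W]
            x._accumulate(gxp)

    return Tensor._node(out, parents, backward)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, padding: int = 1
) -> Tensor:
    """Transposed 2-D convolution; weight layout (Cin, Cout, kh, kw).

    With kernel 4, stride 2, padding 1 the spatial size exactly doubles.
    """
    B, Cin, H, W = x.shape
    Cin_w, Cout, kh, kw = w.shape
    if Cin != Cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: {Cin} vs {Cin_w}")
    Hf = (H - 1) * stride + kh
    Wf = (W - 1) * stride + kw
    yfull = np.zeros((B, Cout, Hf, Wf), dtype=DTYPE)
    xd = x.data
    for ki in range(kh):
        for kj in range(kw):
            yfull[
                :, :, ki : ki + stride * H : stride, kj : kj + stride * W : stride
            ] += np.einsum("bchw,cd->bdhw", xd, w.data[:, :, ki, kj], optimize=True)
    y = yfull[:, :, padding : Hf - padding, padding : Wf - padding]
    if b is not None:
        y = y + b.data[:, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gfull = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        for ki in range(kh):
            for kj in range(kw):
                gslice = gfull[
                    :, :, ki : ki + stride * H : stride, kj : kj + stride * W : stride
                ]
                if x.requires_grad:
                    gx = np.einsum(
                        "bdhw,cd->bchw", gslice, w.data[:, :, ki, kj], optimize=True
                    )
                    if x.grad is None:
                        x.grad = np.zeros(x.shape, dtype=DTYPE)
                    x.grad += gx
                if w.requires_grad:
                    gw = np.einsum("bchw,bdhw->cd", xd, gslice, optimize=True)
                    if w.grad is None:
                        w.grad = np.zeros(w.shape, dtype=DTYPE)
                    w.grad[:, :, ki, kj] += gw

    return Tensor._node(y, parents, backward)
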