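"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tensor engine sufficient for the convolutional / attention blocks
and the detector training loop in this package: broadcasting arithmetic,
matmul, reductions, shape ops, gather, grouped 2-D convolution.  Gradients
are accumulated in float64.  The engine is deliberately eager and
single-threaded; everything in this package is desk-scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def backward(g, out):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(self.data**p, (self,), backward)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        def backward(g, out):
            return (g * out.data,)

        return Tensor._make(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        def backward(g, out):
            return (g * 0.5 / out.data,)

        return Tensor._make(np.sqrt(self.data), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            return (g * out.data * (1.0 - out.data),)

        return Tensor._make(s, (self,), backward)

    def tanh(self):
        def backward(g, out):
            return (g * (1.0 - out.data**2),)

        return Tensor._make(np.tanh(self.data), (self,), backward)

    def relu(self):
        def backward(g, out):
            return (g * (self.data > 0),)

        return Tensor._make(np.maximum(self.data, 0.0), (self,), backward)

    def silu(self):
        return self * self.sigmoid()

    def softplus(self):
        """log(1 + exp(x)), computed stably."""
        z = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))

        def backward(g, out):
            return (g / (1.0 + np.exp(-self.data)),)

        return Tensor._make(z, (self,), backward)

    def atan(self):
        def backward(g, out):
            return (g / (1.0 + self.data**2),)

        return Tensor._make(np.arctan(self.data), (self,), backward)

    def abs(self):
        def backward(g, out):
            return (g * np.sign(self.data),)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        def backward(g, out):
            return (g * ((self.data >= lo) & (self.data <= hi)),)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data >= other.data  # ties route to the first argument

        def backward(g, out):
            return (
                _unbroadcast(g * mask, self.shape),
                _unbroadcast(g * ~mask, other.shape),
            )

        return Tensor._make(np.maximum(self.data, other.data), (self, other), backward)

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        mask = self.data <= other.data

        def backward(g, out):
            return (
                _unbroadcast(g * mask, self.shape),
                _unbroadcast(g * ~mask, other.shape),
            )

        return Tensor._make(np.minimum(self.data, other.data), (self, other), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, out):
            return (g.reshape(self.shape),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, out):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    def take(self, indices: np.ndarray, axis: int):
        """Gather along `axis` with an integer index array (non-differentiable
        in the indices; gradient scatter-adds back)."""
        indices = np.asarray(indices)

        def backward(g, out):
            full = np.zeros_like(self.data)
            sl = [slice(None)] * self.ndim
            src = np.moveaxis(g, axis, 0)
            tgt = np.moveaxis(full, axis, 0)
            np.add.at(tgt, indices.reshape(-1), src.reshape((-1,) + tgt.shape[1:]))
            return (full,)

        return Tensor._make(np.take(self.data, indices, axis=axis), (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            ga = g @ other.data.swapaxes(-1, -2)
            gb = self.data.swapaxes(-1, -2) @ g
            return (
                _unbroadcast(ga, self.shape),
                _unbroadcast(gb, other.shape),
            )

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- backprop ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy() if isinstance(g, np.ndarray) else _as_array(g)
                else:
                    parent.grad = parent.grad + g


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = t if isinstance(t, Tensor) else Tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


# ---------------------------------------------------------------------------
# grouped 2-D convolution via im2col
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return np.ascontiguousarray(windows), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square stride/padding.

    weight: (C_out, C_in/groups, kh, kw); bias: (C_out,) or None.
    """
    n, c, h, w = x.shape
    cout, cg, kh, kw = weight.shape
    if c % groups or cout % groups or cg != c // groups:
        raise ValueError(
            f"channel plan incompatible with groups={groups}: "
            f"input {c}, weight {weight.shape}"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    # (N, G, Cg*kh*kw, Ho*Wo)
    cols_m = cols.reshape(n, groups, cg * kh * kw, ho * wo)
    w_m = weight.data.reshape(groups, cout // groups, cg * kh * kw)
    out = np.matmul(w_m[None], cols_m)  # (N, G, Cout/G, Ho*Wo)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    def backward(g, _out):
        g_m = g.reshape(n, groups, cout // groups, ho * wo)
        gw = np.einsum("ngop,ngkp->gok", g_m, cols_m).reshape(weight.shape)
        gcols = np.matmul(w_m.swapaxes(-1, -2)[None], g_m)  # (N,G,K,P)
        gcols = gcols.reshape(n, c, kh, kw, ho, wo)
        hp, wp = h + 2 * padding, w + 2 * padding
        gx_pad = np.zeros((n, c, hp, wp))
        for i in range(kh):
            for j in range(kw):
                gx_pad[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gcols[:, :, i, j]
        gx = gx_pad[:, :, padding:padding + h, padding:padding + w] if padding else gx_pad
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)
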