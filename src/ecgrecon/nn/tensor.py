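"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the primitives needed by the ECG models are
implemented (broadcast arithmetic, matmul, 1-d convolutions, reductions,
shaping, a handful of nonlinearities).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "where", "conv1d", "conv_transpose1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
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
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None) -> None:
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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        # leaves that are also intermediate outputs
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        out = Tensor._make(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.data.shape),
                       _unbroadcast(g * a.data, b.data.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data, (a, b),
            lambda g: (_unbroadcast(g / b.data, a.data.shape),
                       _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
        )

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,),
            lambda g: (g * p * a.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bwd(g):
            ad, bd = a.data, b.data
            # promote 1-D operands to matrices so the transpose rules apply
            a2 = ad[None, :] if ad.ndim == 1 else ad
            b2 = bd[:, None] if bd.ndim == 1 else bd
            g2 = np.asarray(g)
            if bd.ndim == 1:
                g2 = g2[..., None]
            if ad.ndim == 1:
                g2 = g2[..., None, :]
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            ga = _unbroadcast(ga, a2.shape).reshape(ad.shape)
            gb = _unbroadcast(gb, b2.shape).reshape(bd.shape)
            return ga, gb

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def elu(self, alpha: float = 1.0):
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        out_data = np.where(a.data > 0, a.data, neg)
        return Tensor._make(
            out_data, (a,),
            lambda g: (np.where(a.data > 0, g, g * (neg + alpha)),),
        )

    def abs(self):
        a = self
        s = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * s,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g2, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return Tensor._make(
            np.swapaxes(a.data, ax1, ax2), (a,),
            lambda g: (np.swapaxes(g, ax1, ax2),),
        )

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- composites -----------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def var(self, axis=None, keepdims: bool = False):
        mu = self.mean(axis=axis, keepdims=True)
        d = self - mu
        return (d * d).mean(axis=axis, keepdims=keepdims)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0)[i] for i in range(len(tensors)))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def where(cond, a, b) -> Tensor:
    """Elementwise select; `cond` is a constant boolean array."""
    cond = np.asarray(cond, dtype=bool)
    a = Tensor._coerce(a)
    b = Tensor._coerce(b)

    def bwd(g):
        return (
            _unbroadcast(np.where(cond, g, 0.0), a.data.shape),
            _unbroadcast(np.where(cond, 0.0, g), b.data.shape),
        )

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), bwd)


# -- 1-d convolution primitives ----------------------------------------------

def _conv1d_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (N, Cin, T), w: (Cout, Cin, K) -> (N, Cout, T_out)."""
    n, cin, t = x.shape
    cout, _, k = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    t_out = (x.shape[-1] - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)[:, :, ::stride]
    # windows: (N, Cin, T_out, K)
    return np.einsum("nitk,oik->not", windows, w, optimize=True)


def _conv1d_bwd_x(g: np.ndarray, w: np.ndarray, stride: int, pad: int,
                  t_in: int) -> np.ndarray:
    """Gradient of conv1d w.r.t. input; also the conv-transpose forward map."""
    n, cout, t_out = g.shape
    _, cin, k = w.shape
    xg = np.zeros((n, cin, t_in + 2 * pad))
    contrib = np.einsum("not,oik->nitk", g, w, optimize=True)  # (N,Cin,T_out,K)
    for j in range(k):
        idx = np.arange(t_out) * stride + j
        np.add.at(xg, (slice(None), slice(None), idx), contrib[:, :, :, j])
    if pad:
        xg = xg[:, :, pad:xg.shape[-1] - pad]
    return xg


def _conv1d_bwd_w(g: np.ndarray, x: np.ndarray, stride: int, pad: int,
                  k: int) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)[:, :, ::stride]
    return np.einsum("not,nitk->oik", g, windows, optimize=True)


def conv1d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    t_in = x.data.shape[-1]
    k = w.data.shape[-1]

    def bwd(g):
        return (
            _conv1d_bwd_x(g, w.data, stride, pad, t_in),
            _conv1d_bwd_w(g, x.data, stride, pad, k),
        )

    return Tensor._make(_conv1d_fwd(x.data, w.data, stride, pad), (x, w), bwd)


def conv_transpose1d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0,
                     output_padding: int = 0) -> Tensor:
    """x: (N, Cout, T), w: (Cout, Cin, K) -> (N, Cin, T_up).

    Exactly the adjoint of :func:`conv1d`, so the weight layout mirrors the
    forward convolution it inverts.  T_up = (T-1)*stride + K - 2*pad + output_padding.
    """
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    t = x.data.shape[-1]
    k = w.data.shape[-1]
    t_up = (t - 1) * stride + k - 2 * pad + output_padding

    def fwd(xd, wd):
        out = _conv1d_bwd_x(xd, wd, stride, pad, t_up)
        return out

    def bwd(g):
        gx = _conv1d_fwd(g, w.data, stride, pad)
        gx = gx[:, :, : t]
        gw = _conv1d_bwd_w(x.data, g, stride, pad, k)
        return gx, gw

    return Tensor._make(fwd(x.data, w.data), (x, w), bwd)
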