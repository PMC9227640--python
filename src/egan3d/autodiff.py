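"""Reverse-mode automatic differentiation on numpy arrays.

This is the differentiation core of the package: a small tape-based
autograd engine whose only array type is :class:`Tensor`, a thin wrapper
around an ``ndarray`` with a gradient slot and a backward closure.  It
implements exactly the operations the translation network needs --
elementwise arithmetic, the tanh/sigmoid/leaky-ReLU nonlinearities,
axis reductions, shape manipulation, a two-operand ``einsum`` for the
separable (single-axis) convolutions of the encoder, and im2col-based
2D/3D convolutions that route the heavy contraction through BLAS.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the tape.  Broadcasting in elementwise ops is
supported; the gradient is summed back to the operand's shape.

Every operation here is verified against central finite differences in
the test-suite, so the network layers built on top can be trusted to the
precision of the float type in use (the network runs in float32; the
gradient checks run in float64).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # added leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    # -- graph construction helpers ----------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    # -- nonlinearities ------------------------------------------------------
    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(np.where(mask, g, slope * g))

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        r = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / r)

        return self._make(r, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def broadcast_to(self, shape):
        out_data = np.broadcast_to(self.data, shape)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))

        return self._make(out_data, (self,), backward)

    # -- contractions ---------------------------------------------------------
    def einsum(self, subscript: str, other: "Tensor") -> "Tensor":
        """Two-operand einsum ``subscript`` = ``"ab,bc->ac"`` style.

        Requires every index of each operand to appear in the output or in
        the other operand (true for all convolution-style contractions),
        so each gradient is itself an einsum.
        """
        other = self._lift(other)
        lhs, out_sub = subscript.split("->")
        a_sub, b_sub = lhs.split(",")
        out_data = np.einsum(subscript, self.data, other.data, optimize=True)

        def backward(g):
            if self.requires_grad:
                ga = np.einsum(
                    f"{out_sub},{b_sub}->{a_sub}", g, other.data, optimize=True
                )
                self._accum(ga)
            if other.requires_grad:
                gb = np.einsum(
                    f"{out_sub},{a_sub}->{b_sub}", g, self.data, optimize=True
                )
                other._accum(gb)

        return self._make(out_data, (self, other), backward)

    def conv3d(self, weight: "Tensor", stride: int = 1, padding: int = 0) -> "Tensor":
        """3D cross-correlation, x:[N,C,D,H,W] * w:[O,C,kd,kh,kw] -> [N,O,D',H',W']."""
        return _conv_nd(self, weight, stride, padding, nd=3)

    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0) -> "Tensor":
        """2D cross-correlation, x:[N,C,H,W] * w:[O,C,kh,kw] -> [N,O,H',W']."""
        return _conv_nd(self, weight, stride, padding, nd=2)

    # -- backward pass ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
               var: np.ndarray, eps: float, use_batch_stats: bool) -> Tensor:
    """Fused batch normalisation over all axes except the channel axis (1).

    ``mean``/``var`` are the statistics actually used (batch statistics in
    training, running estimates in eval); ``use_batch_stats`` selects the
    matching backward rule.  Fusing avoids a chain of large temporaries.
    """
    axes = (0,) + tuple(range(2, x.ndim))
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out_data = gamma.data * xhat + beta.data
    m = x.data.size // x.shape[1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            if use_batch_stats:
                g_mean = g.mean(axis=axes, keepdims=True)
                gx_mean = (g * xhat).sum(axis=axes, keepdims=True) / m
                x._accum(gamma.data * inv_std * (g - g_mean - xhat * gx_mean))
            else:
                x._accum(gamma.data * inv_std * g)

    out = Tensor(out_data, requires_grad=(x.requires_grad or gamma.requires_grad
                                          or beta.requires_grad))
    if out.requires_grad:
        out._prev = (x, gamma, beta)
        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``; gradient splits back."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)

        def backward(g):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(gpart)

        out._backward = backward
    return out


def _conv_nd(x: Tensor, w: Tensor, stride: int, padding: int, nd: int) -> Tensor:
    """Shared convolution dispatch.

    Stride-1 convolutions use a shift-accumulate scheme (one channel-mixing
    einsum per kernel offset, no im2col materialisation); strided ones go
    through im2col + one BLAS matmul.
    """
    if stride == 1:
        return _conv_shift(x, w, padding, nd)
    return _conv_im2col(x, w, stride, padding, nd)


def _conv_shift(x: Tensor, w: Tensor, padding: int, nd: int) -> Tensor:
    w = Tensor._lift(w)
    ksize = w.shape[2:]
    if padding:
        pad = [(0, 0), (0, 0)] + [(padding, padding)] * nd
        xp = np.pad(x.data, pad, mode="constant")
    else:
        xp = x.data
    out_spatial = tuple(s - k + 1 for s, k in zip(xp.shape[2:], ksize))
    cout, cin = w.shape[0], w.shape[1]
    kvol = int(np.prod(ksize))
    wf = w.data.reshape(cout, cin, kvol)
    sub_sp = "dhw"[:nd]
    sub_fwd = f"oc,nc{sub_sp}->no{sub_sp}"
    out_data = None
    offsets = [np.unravel_index(f, ksize) for f in range(kvol)]
    slices = [
        (slice(None), slice(None)) + tuple(slice(o, o + s) for o, s in zip(off, out_spatial))
        for off in offsets
    ]
    for f, sl in enumerate(slices):
        term = np.einsum(sub_fwd, wf[:, :, f], xp[sl], optimize=True)
        out_data = term if out_data is None else out_data + term

    def backward(g):
        if w.requires_grad:
            gw = np.empty((cout, cin, kvol), dtype=w.data.dtype)
            sub_w = f"no{sub_sp},nc{sub_sp}->oc"
            for f, sl in enumerate(slices):
                gw[:, :, f] = np.einsum(sub_w, g, xp[sl], optimize=True)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            sub_x = f"oc,no{sub_sp}->nc{sub_sp}"
            for f, sl in enumerate(slices):
                gxp[sl] += np.einsum(sub_x, wf[:, :, f], g, optimize=True)
            if padding:
                inner = (slice(None), slice(None)) + tuple(
                    slice(padding, padding + s) for s in x.shape[2:]
                )
                gxp = gxp[inner]
            x._accum(gxp)

    out = Tensor(out_data, requires_grad=(x.requires_grad or w.requires_grad))
    if out.requires_grad:
        out._prev = (x, w)
        out._backward = backward
    return out


def _conv_im2col(x: Tensor, w: Tensor, stride: int, padding: int, nd: int) -> Tensor:
    w = Tensor._lift(w)
    ksize = w.shape[2:]
    if padding:
        pad = [(0, 0), (0, 0)] + [(padding, padding)] * nd
        xp = np.pad(x.data, pad, mode="constant")
    else:
        xp = x.data
    spatial_axes = tuple(range(2, 2 + nd))
    win = sliding_window_view(xp, ksize, axis=spatial_axes)
    # win: [N, C, *out_spatial, *ksize]; apply stride on the spatial axes
    if stride > 1:
        sl = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
        win = win[sl]
    n = x.shape[0]
    cin = x.shape[1]
    out_spatial = win.shape[2 : 2 + nd]
    kvol = int(np.prod(ksize))
    cout = w.shape[0]
    # [N, *sp, C*kvol] @ [C*kvol, O]
    win_mat = np.ascontiguousarray(np.moveaxis(win, 1, 1 + nd)).reshape(
        n * int(np.prod(out_spatial)), cin * kvol
    )
    w_mat = w.data.reshape(cout, cin * kvol).T
    out_data = (win_mat @ w_mat).reshape((n, *out_spatial, cout))
    out_data = np.moveaxis(out_data, -1, 1)

    def backward(g):
        g_mat = np.moveaxis(g, 1, -1).reshape(n * int(np.prod(out_spatial)), cout)
        if w.requires_grad:
            gw = (g_mat.T @ win_mat).reshape((cout, cin) + tuple(ksize))
            w._accum(gw)
        if x.requires_grad:
            # scatter-add: for each kernel offset, place g*w back on the input grid
            gxp = np.zeros_like(xp)
            gw_full = (g_mat @ w_mat.T).reshape((n, *out_spatial, cin, kvol))
            gw_full = np.moveaxis(gw_full, 1 + nd, 1)  # [N, C, *sp, kvol]
            for flat in range(kvol):
                off = np.unravel_index(flat, ksize)
                sl = (slice(None), slice(None)) + tuple(
                    slice(o, o + stride * s, stride)
                    for o, s in zip(off, out_spatial)
                )
                gxp[sl] += gw_full[..., flat]
            if padding:
                sl = (slice(None), slice(None)) + tuple(
                    slice(padding, padding + s) for s in x.shape[2:]
                )
                gxp = gxp[sl]
            x._accum(gxp)

    out = Tensor(out_data, requires_grad=(x.requires_grad or w.requires_grad))
    if out.requires_grad:
        out._prev = (x, w)
        out._backward = backward
    return out
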