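"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides the small tensor engine the network code in this
package is built on: a :class:`Tensor` wrapping an ``ndarray`` plus the
operations needed for graph-convolutional and convolutional classifiers
(broadcast arithmetic, matmul, 2-D convolution with groups/stride/padding,
reductions, reshaping, concatenation and the usual activations).

Gradients are accumulated by a topological backward sweep from the output
node.  The op set is deliberately closed over what the models in this
package use; it is not a general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "concat", "stack"]

#: When set to a list, forward conv2d/matmul calls append
#: ``(op_kind, multiply_add_count)`` records to it (see complexity reporting).
MAC_RECORDER: list | None = None


def _record_macs(kind: str, macs: int):
    if MAC_RECORDER is not None:
        MAC_RECORDER.append((kind, int(macs)))


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- bookkeeping ----------------------------------------------------
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
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def _scalar_affine(self, a: float, b: float):
        """a * self + b with python-scalar (weak) promotion, dtype-preserving."""
        out_data = self.data * a + b if b else self.data * a

        def bw(g):
            if self.requires_grad:
                self._accum(g * a if a != 1 else g)

        return Tensor._make(out_data, (self,), bw)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_affine(1.0, other)
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_affine(other, 0.0)
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_affine(1.0, -other)
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_affine(-1.0, other)
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_affine(1.0 / other, 0.0)
        other = _as_tensor(other)
        return self * other._reciprocal()

    def __rtruediv__(self, other):
        return _as_tensor(other) * self._reciprocal()

    def _reciprocal(self):
        out_data = 1.0 / self.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(-g * out_data * out_data, self.shape))

        return Tensor._make(out_data, (self,), bw)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        if MAC_RECORDER is not None:
            batch = int(np.prod(out_data.shape[:-2])) if out_data.ndim > 2 else 1
            _record_macs("matmul", batch * out_data.shape[-2] * out_data.shape[-1]
                         * self.data.shape[-1])

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- shaping --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along a single axis; gradient flows to the (first) argmax."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient check stays symmetric
        norm = mask.sum(axis=axis, keepdims=True)

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * (gg / norm))

        res = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(res, (self,), bw)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        # evaluated via the positive branch to avoid exp overflow
        z = np.exp(-np.abs(self.data))
        out_data = np.where(self.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis` (differentiable)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), padding=(0, 0), groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    x: (N, C, H, W); w: (O, C // groups, kh, kw); b: (O,) or None.
    Implemented with a strided sliding-window view + einsum; the input
    gradient is scattered back per kernel offset.
    """
    sh, sw = stride
    ph, pw = padding
    N, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    G = groups
    if C != Cg * G or O % G:
        raise ValueError(f"conv2d channel mismatch: x{x.shape}, w{w.shape}, groups={G}")
    Og = O // G
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    depthwise = (Cg == 1 and Og == 1)
    dtype = np.result_type(x.data, w.data)

    def offset_slice(arr, u, v):
        return arr[:, :, u:u + sh * Ho:sh, v:v + sw * Wo:sw]

    # accumulate one batched matmul (or broadcast multiply, if depthwise)
    # per kernel offset: avoids materializing the full im2col buffer
    flat_out = G == 1 or depthwise
    out = np.zeros((N, O, Ho * Wo) if flat_out else (N, G, Og, Ho * Wo), dtype=dtype)
    for u in range(kh):
        for v in range(kw):
            xs = offset_slice(xp, u, v)               # (N, C, Ho, Wo) view
            if depthwise:
                out += (w.data[:, 0, u, v][None, :, None]
                        * xs.reshape(N, C, Ho * Wo))
            elif G == 1:
                out += np.matmul(w.data[:, :, u, v], xs.reshape(N, C, Ho * Wo))
            else:
                xs_g = xs.reshape(N, G, Cg, Ho * Wo)
                w_uv = w.data.reshape(G, Og, Cg, kh, kw)[..., u, v]
                out += np.matmul(w_uv, xs_g)
    out = out.reshape(N, O, Ho, Wo)
    _record_macs("conv2d", N * O * Ho * Wo * Cg * kh * kw)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def bw(g):
        gf = g.reshape(N, O, Ho * Wo) if flat_out else g.reshape(N, G, Og, Ho * Wo)
        need_x = x.requires_grad
        gxp = np.zeros_like(xp, dtype=g.dtype) if need_x else None
        gw = np.zeros_like(w.data, dtype=g.dtype) if w.requires_grad else None
        for u in range(kh):
            for v in range(kw):
                xs = offset_slice(xp, u, v)
                if depthwise:
                    gmap = g * xs                      # (N, C, Ho, Wo)
                    if gw is not None:
                        gw[:, 0, u, v] += gmap.sum(axis=(0, 2, 3))
                    if need_x:
                        offset_slice(gxp, u, v)[...] += \
                            w.data[:, 0, u, v][None, :, None, None] * g
                elif G == 1:
                    xs_f = xs.reshape(N, C, Ho * Wo)
                    if gw is not None:
                        gw[:, :, u, v] += np.matmul(
                            gf, xs_f.swapaxes(1, 2)).sum(axis=0)
                    if need_x:
                        contrib = np.matmul(w.data[:, :, u, v].T, gf)
                        offset_slice(gxp, u, v)[...] += \
                            contrib.reshape(N, C, Ho, Wo)
                else:
                    xs_g = xs.reshape(N, G, Cg, Ho * Wo)
                    w_uv = w.data.reshape(G, Og, Cg, kh, kw)[..., u, v]
                    if gw is not None:
                        gw.reshape(G, Og, Cg, kh, kw)[..., u, v] += np.matmul(
                            gf, xs_g.swapaxes(-1, -2)).sum(axis=0)
                    if need_x:
                        contrib = np.matmul(w_uv.swapaxes(-1, -2), gf)
                        offset_slice(gxp, u, v)[...] += \
                            contrib.reshape(N, C, Ho, Wo)
        if gw is not None:
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if need_x:
            trimmed = gxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gxp
            x._accum(trimmed)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)
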