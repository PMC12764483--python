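"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` records the
operation that produced it and a closure that accumulates gradients into its
parents.  Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back to the operand's shape.  Only the operations the
bundle-mapping network needs are implemented.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are created with (float32 or float64).

    float32 roughly halves training time at these problem sizes; float64 is
    used for finite-difference gradient verification.
    """
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.float32, np.float64):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype.type


def get_default_dtype():
    return _DEFAULT_DTYPE


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
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient and autodiff history."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(parents)
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- introspection -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autodiff ------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
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

        visit(self)
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        return Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return Tensor._from_op(
            self.data / other.data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Tensor._from_op(
            self.data**p,
            (self,),
            lambda g: [(self, g * p * self.data ** (p - 1))],
        )

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return [
                (self, _unbroadcast(ga, self.shape)),
                (other, _unbroadcast(gb, other.shape)),
            ]

        return Tensor._from_op(a @ b, (self, other), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: [(self, g.reshape(old))]
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes),
            (self,),
            lambda g: [(self, g.transpose(inv))],
        )

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return [(self, out)]

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.shape).copy())]
            g2 = g if keepdims else np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g2, self.shape).copy())]

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None):
        """Max reduction; gradient flows to the (first) argmax element."""
        data = self.data.max(axis=axis)

        def backward(g):
            out = np.zeros_like(self.data)
            if axis is None:
                idx = np.unravel_index(int(np.argmax(self.data)), self.shape)
                out[idx] = g
            else:
                idx = np.argmax(self.data, axis=axis)
                np.put_along_axis(
                    out, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
                )
            return [(self, out)]

        return Tensor._from_op(data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: [(self, g * out_data)])

    def log(self):
        return Tensor._from_op(
            np.log(self.data), (self,), lambda g: [(self, g / self.data)]
        )

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(
            out_data, (self,), lambda g: [(self, g * 0.5 / out_data)]
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(
            np.where(mask, self.data, 0.0), (self,), lambda g: [(self, g * mask)]
        )

    def leaky_relu(self, alpha: float = 0.1):
        mask = self.data > 0
        slope = np.where(mask, 1.0, alpha)
        return Tensor._from_op(
            self.data * slope, (self,), lambda g: [(self, g * slope)]
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(
            out_data, (self,), lambda g: [(self, g * (1.0 - out_data**2))]
        )

    def sigmoid(self):
        # tanh form avoids exp overflow in float32
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._from_op(
            out_data, (self,), lambda g: [(self, g * out_data * (1.0 - out_data))]
        )

    def clamp(self, lo: float, hi: float):
        """Hard clamp; gradient is zero outside [lo, hi] (straight blocking)."""
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._from_op(
            np.clip(self.data, lo, hi), (self,), lambda g: [(self, g * mask)]
        )


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv_nd(x: Tensor, weight: Tensor, bias: Tensor, kernel: int, stride: int) -> Tensor:
    """N-dimensional convolution via shift-and-accumulate.

    ``x`` is (N, C_in, *S) with 1 <= len(S) <= 3 (already padded by the
    caller); ``weight`` is (C_in * kernel**nd, C_out) with offsets ordered
    as ``itertools.product`` over the spatial axes; ``bias`` is (C_out,).
    One tensordot per kernel offset over strided slices — far cheaper than
    materializing im2col patches at these problem sizes.
    """
    import itertools

    nd = x.ndim - 2
    n, c_in = x.shape[:2]
    spatial = x.shape[2:]
    c_out = weight.shape[1]
    s_out = tuple((s - kernel) // stride + 1 for s in spatial)
    w = weight.data.reshape((c_in,) + (kernel,) * nd + (c_out,))
    offsets = list(itertools.product(range(kernel), repeat=nd))

    def off_slices(off):
        return (slice(None), slice(None)) + tuple(
            slice(o, o + stride * (so - 1) + 1, stride) for o, so in zip(off, s_out)
        )

    def off_slices_last(off):
        # channels-last layout (N, *S, C): spatial axes 1..nd
        return (slice(None),) + tuple(
            slice(o, o + stride * (so - 1) + 1, stride) for o, so in zip(off, s_out)
        ) + (slice(None),)

    x_last = np.ascontiguousarray(np.moveaxis(x.data, 1, -1))  # (N, *S, C_in)
    out = np.zeros((n,) + s_out + (c_out,), dtype=x.data.dtype)
    for off in offsets:
        xs = x_last[off_slices_last(off)]  # (N, *S_out, C_in)
        wo = w[(slice(None),) + off]  # (C_in, C_out)
        out += xs @ wo
    out += bias.data
    out = np.moveaxis(out, -1, 1)  # (N, C_out, *S_out)

    sum_axes = tuple(range(nd + 1))  # batch + spatial axes in channels-last

    def backward(g):
        gt = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # (N, *S_out, C_out)
        grad_b = gt.reshape(-1, c_out).sum(axis=0)
        grad_w = np.empty_like(w)
        grad_x_last = np.zeros_like(x_last)
        for off in offsets:
            sl = off_slices_last(off)
            xs = x_last[sl]
            grad_w[(slice(None),) + off] = np.tensordot(
                xs, gt, axes=(sum_axes, sum_axes)
            )
            wo = w[(slice(None),) + off]
            grad_x_last[sl] += gt @ wo.T
        return [
            (x, np.moveaxis(grad_x_last, -1, 1)),
            (weight, grad_w.reshape(weight.shape)),
            (bias, grad_b),
        ]

    return Tensor._from_op(out, (x, weight, bias), backward)


def pad_nd(x: Tensor, pad: int, spatial_axes: tuple[int, ...]) -> Tensor:
    """Zero-pad ``pad`` cells on both sides of each spatial axis."""
    if pad == 0:
        return x
    widths = [(0, 0)] * x.ndim
    for ax in spatial_axes:
        widths[ax] = (pad, pad)
    slices = tuple(
        slice(pad, -pad) if ax in spatial_axes else slice(None)
        for ax in range(x.ndim)
    )
    return Tensor._from_op(
        np.pad(x.data, widths), (x,), lambda g: [(x, g[slices])]
    )


def upsample_nearest(x: Tensor, factor: int, spatial_axes: tuple[int, ...]) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor along given axes."""
    data = x.data
    for ax in spatial_axes:
        data = np.repeat(data, factor, axis=ax)

    def backward(g):
        for ax in spatial_axes:
            shp = list(g.shape)
            shp[ax] = shp[ax] // factor
            shp.insert(ax + 1, factor)
            g = g.reshape(shp).sum(axis=ax + 1)
        return [(x, g)]

    return Tensor._from_op(data, (x,), backward)
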