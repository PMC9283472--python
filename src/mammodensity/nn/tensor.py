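"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by the segmentation network and its losses are
implemented: broadcasting arithmetic, exp/log/pow, reductions, ReLU,
concatenation, basic indexing, stride-1 dilated 2-D convolution (im2col),
stride-2 transpose convolution and 2x2 max pooling.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` over an
iteratively built topological order, so deep graphs do not hit the Python
recursion limit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
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

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- graph construction ----------------------------------------------
    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)

        return Tensor._op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._op(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)

        return Tensor._op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g / b.data)
            if b.requires_grad:
                b._accum(-g * a.data / (b.data * b.data))

        return Tensor._op(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._op(out_data, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._op(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._op(np.log(a.data), (a,), bwd)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._op(a.data * mask, (a,), bwd)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bwd(g):
            a._accum(np.asarray(g).reshape(old))

        return Tensor._op(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(np.transpose(g, inv))

        return Tensor._op(np.transpose(a.data, axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._op(a.data[idx], (a,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


# -- convolution primitives ------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(xp: np.ndarray, k: int, d: int) -> np.ndarray:
    """(B,C,Hp,Wp) padded input -> contiguous (B, C*k*k, H*W) columns."""
    b, c, hp, wp = xp.shape
    h, w = hp - d * (k - 1), wp - d * (k - 1)
    cols = np.empty((b, c, k, k, h, w), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i * d:i * d + h, j * d:j * d + w]
    return cols.reshape(b, c * k * k, h * w)


def _corr2d(x: np.ndarray, w: np.ndarray, d: int):
    """Stride-1 'same' correlation of (B,C,H,W) with (O,C,k,k); returns (out, cols)."""
    k = w.shape[-1]
    p = d * (k - 1) // 2
    cols = _im2col(_pad_hw(x, p), k, d)
    wmat = w.reshape(w.shape[0], -1)
    out = np.matmul(wmat, cols).reshape(x.shape[0], w.shape[0], x.shape[2], x.shape[3])
    return out, cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 'same'-padded 2-D convolution (cross-correlation convention).

    `x`: (B, C, H, W); `w`: (O, C, k, k) with odd k; `b`: (O,) or None.
    Padding is dilation*(k-1)//2 so spatial size is preserved for any
    dilation rate.
    """
    x, w = Tensor._lift(x), Tensor._lift(w)
    k = w.data.shape[-1]
    out_data, cols = _corr2d(x.data, w.data, dilation)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        bsz, o = g.shape[:2]
        gflat = g.reshape(bsz, o, -1)
        if w.requires_grad:
            dw = np.matmul(gflat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # input gradient = correlation of g with the spatially flipped
            # kernel, channel axes swapped, same dilation and padding
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dx, _ = _corr2d(g, np.ascontiguousarray(wflip), dilation)
            x._accum(dx)

    return Tensor._op(out_data, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2, kernel-2 transpose convolution (exact 2x upsampling).

    `x`: (B, C, H, W); `w`: (C, O, 2, 2) -> output (B, O, 2H, 2W).  Each
    input pixel scatters into a disjoint 2x2 output block, so forward and
    backward are plain einsums with no overlap handling.
    """
    x, w = Tensor._lift(x), Tensor._lift(w)
    bsz, c, h, wd = x.data.shape
    o = w.data.shape[1]
    # (B,C,H,W) -> (B*H*W, C) @ (C, O*4) -> (B,H,W,O,2,2) -> (B,O,2H,2W)
    xmat = x.data.transpose(0, 2, 3, 1).reshape(-1, c)
    wmat = w.data.reshape(c, -1)
    out6 = (xmat @ wmat).reshape(bsz, h, wd, o, 2, 2)
    out_data = np.ascontiguousarray(
        out6.transpose(0, 3, 1, 4, 2, 5)).reshape(bsz, o, 2 * h, 2 * wd)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        # gather g back to (B*H*W, O*4) matching the forward layout
        g6 = g.reshape(bsz, o, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        gmat = np.ascontiguousarray(g6).reshape(-1, o * 4)
        if x.requires_grad:
            dx = (gmat @ wmat.T).reshape(bsz, h, wd, c)
            x._accum(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            w._accum((xmat.T @ gmat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._op(out_data, parents, bwd)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties resolved to the first (row-major) max."""
    x = Tensor._lift(x)
    bsz, c, h, w = x.data.shape
    xr = x.data.reshape(bsz, c, h // 2, 2, w // 2, 2)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(bsz, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(bsz, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(bsz, c, h, w))

    return Tensor._op(out_data, (x,), bwd)
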