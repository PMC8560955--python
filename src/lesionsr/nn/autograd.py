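"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape: each op builds a :class:`Tensor` holding the
forward value and a closure that accumulates gradients into its parents.
Only the operations needed by the super-resolution networks are provided
(broadcast-aware arithmetic, reductions, matmul, 2D convolution via
im2col, padding/cropping/flipping for the transposed convolution, channel
concatenation, leaky ReLU, dropout, spatial pyramid max pooling).

Float32 throughout; gradients match the forward dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "spp_pool", "leaky_relu", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic (broadcast-aware) -----------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), backward)

    def sqrt(self):
        return self**0.5

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).astype(np.float32))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def flip(self, axes):
        def backward(g):
            self._accum(np.flip(g, axes))

        return Tensor._make(np.flip(self.data, axes).copy(), (self,), backward)

    def pad2d(self, pad: tuple[int, int, int, int]):
        """Zero-pad the last two axes by (top, bottom, left, right)."""
        t, b, l, r = pad
        widths = [(0, 0)] * (self.data.ndim - 2) + [(t, b), (l, r)]

        def backward(g):
            sl = [slice(None)] * (g.ndim - 2) + [
                slice(t, g.shape[-2] - b if b else None),
                slice(l, g.shape[-1] - r if r else None),
            ]
            self._accum(g[tuple(sl)])

        return Tensor._make(np.pad(self.data, widths), (self,), backward)

    def crop2d(self, hw: tuple[int, int]):
        """Keep the top-left (h, w) window of the last two axes."""
        h, w = hw
        old = self.shape

        def backward(g):
            buf = np.zeros(old, dtype=np.float32)
            buf[..., :h, :w] = g
            self._accum(buf)

        return Tensor._make(self.data[..., :h, :w].copy(), (self,), backward)

    def slice2d(self, rows: slice, cols: slice):
        """Slice the last two axes (used for finite differences)."""
        old = self.shape

        def backward(g):
            buf = np.zeros(old, dtype=np.float32)
            buf[..., rows, cols] = g
            self._accum(buf)

        return Tensor._make(self.data[..., rows, cols].copy(), (self,), backward)

    def zero_upsample2d(self, stride: int):
        """Insert stride-1 zeros between pixels of the last two axes."""
        *lead, h, w = self.shape
        out = np.zeros((*lead, h * stride, w * stride), dtype=np.float32)
        out[..., ::stride, ::stride] = self.data

        def backward(g):
            self._accum(g[..., ::stride, ::stride])

        return Tensor._make(out, (self,), backward)

    def matmul(self, other: "Tensor"):
        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation: x (N,C,H,W) with w (Cout,Cin,kh,kw) + bias."""
    n, c, h, wd = x.shape
    cout, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride)
    out = np.einsum("ocij,ncijhw->nohw", w.data, cols, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        w._accum(np.einsum("nohw,ncijhw->ocij", g, cols, optimize=True))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("ocij,nohw->ncijhw", w.data, g, optimize=True)
            dxp = np.zeros_like(xp)
            ho, wo = g.shape[-2:]
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out, parents, backward)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, slope).astype(np.float32)

    def backward(g):
        x._accum(g * scale)

    return Tensor._make(x.data * scale, (x,), backward)


def dropout(x: Tensor, p_drop: float, rng: np.random.Generator, training: bool = True) -> Tensor:
    """Inverted dropout: active only in training mode; identity otherwise."""
    if not training or p_drop == 0.0:
        return x
    if not 0.0 <= p_drop < 1.0:
        raise ValueError("dropout probability must be in [0, 1)")
    keep = (rng.random(x.shape) >= p_drop).astype(np.float32) / (1.0 - p_drop)

    def backward(g):
        x._accum(g * keep)

    return Tensor._make(x.data * keep, (x,), backward)


def _spp_bounds(size: int, level: int) -> list[tuple[int, int]]:
    """Near-equal cell boundaries: cell c covers [floor(c*size/l), floor((c+1)*size/l))."""
    return [
        (int(np.floor(c * size / level)), int(np.floor((c + 1) * size / level)))
        for c in range(level)
    ]


def spp_pool(x: Tensor, levels: tuple[int, ...]) -> Tensor:
    """Spatial pyramid max pooling: (N,C,H,W) -> (N, C * sum(l^2)).

    For each pyramid level l the map is tiled into l x l near-equal cells
    and the max taken per cell; the concatenated descriptor length depends
    only on C and the levels, never on H or W.
    """
    n, c, h, w = x.shape
    if min(h, w) < max(levels):
        raise ValueError(
            f"spatial size {(h, w)} smaller than max pyramid level {max(levels)}"
        )
    chunks = []
    argmaxes = []  # (level, cell slices, flat argmax) for backward
    for level in levels:
        rows = _spp_bounds(h, level)
        cols = _spp_bounds(w, level)
        for r0, r1 in rows:
            for c0, c1 in cols:
                cell = x.data[:, :, r0:r1, c0:c1].reshape(n, c, -1)
                am = cell.argmax(axis=2)
                chunks.append(cell.max(axis=2))
                argmaxes.append((r0, r1, c0, c1, am))
    out = np.stack(chunks, axis=2).reshape(n, c * len(chunks))

    def backward(g):
        gg = g.reshape(n, c, len(chunks))
        dx = np.zeros_like(x.data)
        ni, ci = np.indices((n, c))
        for k, (r0, r1, c0, c1, am) in enumerate(argmaxes):
            cw = c1 - c0
            rr = r0 + am // cw
            cc = c0 + am % cw
            np.add.at(dx, (ni, ci, rr, cc), gg[:, :, k])
        x._accum(dx)

    return Tensor._make(out, (x,), backward)
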