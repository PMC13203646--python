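"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the 3D autoencoder and diffusion U-Net need:
broadcasting arithmetic, matmul, reshape/transpose/concat, reductions,
elementwise nonlinearities, softmax, strided 3D convolution (im2col), and
nearest-neighbour 3D upsampling.  Gradients are accumulated by a topological
backward sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "slice_channels", "upsample_nearest3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, float(g)))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def silu(self):
        """SiLU / Swish: x * sigmoid(x)."""
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (sig + self.data * sig * (1.0 - sig)))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution (cross-correlation), NCDHW layout.

    weight: (Cout, Cin, kd, kh, kw); bias: (Cout,) or None.  Implemented as
    a sum of kernel-offset-shifted GEMMs, which keeps memory traffic close
    to the input size (no im2col materialization).
    """
    cout, cin, kd, kh, kw = weight.shape
    n = x.shape[0]
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    else:
        xp = x.data
    s = stride
    do = (xp.shape[2] - kd) // s + 1
    ho = (xp.shape[3] - kh) // s + 1
    wo = (xp.shape[4] - kw) // s + 1

    p_out = do * ho * wo
    offsets = [(a, b, c) for a in range(kd) for b in range(kh) for c in range(kw)]

    def shifted2d(a, b, c):
        sh = xp[:, :, a:a + do * s:s, b:b + ho * s:s, c:c + wo * s:s]
        return np.ascontiguousarray(sh).reshape(n, cin, p_out)

    out2d = np.zeros((n, cout, p_out), dtype=xp.dtype)
    for a, b, c in offsets:
        # (Cout,Cin) @ (N,Cin,P) -> (N,Cout,P), BLAS-backed per offset
        out2d += weight.data[:, :, a, b, c] @ shifted2d(a, b, c)
    out_data = out2d.reshape(n, cout, do, ho, wo)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1, 1)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        need_x = x.requires_grad
        g2d = np.ascontiguousarray(g).reshape(n, cout, p_out)
        gxp = np.zeros_like(xp) if need_x else None
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
        for a, b, c in offsets:
            if weight.requires_grad:
                gw[:, :, a, b, c] = (g2d @ shifted2d(a, b, c).transpose(0, 2, 1)) \
                    .sum(axis=0)
            if need_x:
                gx2d = weight.data[:, :, a, b, c].T @ g2d  # (N,Cin,P)
                gxp[:, :, a:a + do * s:s, b:b + ho * s:s, c:c + wo * s:s] += \
                    gx2d.reshape(n, cin, do, ho, wo)
        if weight.requires_grad:
            weight._accumulate(gw)
        if need_x:
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out_t = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out_t.requires_grad = True
        out_t._parents = parents
        out_t._backward = backward
    return out_t


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    """Select channels [start, stop) of an NC... tensor."""
    out_data = x.data[:, start:stop]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, start:stop] = g
            x._accumulate(gx)

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the three spatial axes (NCDHW)."""
    f = factor
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def backward(g):
        if x.requires_grad:
            n, c, d, h, w = x.shape
            gr = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
            x._accumulate(gr)

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out
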