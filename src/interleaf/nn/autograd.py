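"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; calling :meth:`Tensor.backward` on a scalar result accumulates
gradients into every reachable tensor with ``requires_grad`` (or with
``retain_grad`` set, which is how Grad-CAM reads gradients at an
intermediate feature map). The operator set is exactly what the package's
models need: broadcast arithmetic, matmul, slicing/padding/reshaping,
concatenation, reductions, elementwise nonlinearities, softmax and an
im2col 2-D convolution.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv2d", "as_tensor"]


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
    return grad


class Tensor:
    __slots__ = ("data", "requires_grad", "retain_grad", "grad",
                 "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.retain_grad = False
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
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
            if node.retain_grad or node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._node(
            self.data + other.data, (self, other),
            lambda g: ((self, _unbroadcast(g, self.shape)),
                       (other, _unbroadcast(g, other.shape))))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._node(
            self.data * other.data, (self, other),
            lambda g: ((self, _unbroadcast(g * other.data, self.shape)),
                       (other, _unbroadcast(g * self.data, other.shape))))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._node(
            self.data / other.data, (self, other),
            lambda g: ((self, _unbroadcast(g / other.data, self.shape)),
                       (other, _unbroadcast(-g * self.data / other.data**2,
                                            other.shape))))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._node(
            self.data ** e, (self,),
            lambda g: ((self, g * e * self.data ** (e - 1.0)),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape)))

        return Tensor._node(a @ b, (self, other), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._node(self.data.reshape(shape), (self,),
                            lambda g: ((self, g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        return Tensor._node(self.data.transpose(axes), (self,),
                            lambda g: ((self, g.transpose(inverse)),))

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return ((self, full),)
        return Tensor._node(self.data[key], (self,), backward)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for ``numpy.pad``."""
        pw = tuple((int(a), int(b)) for a, b in pad_width)
        slices = tuple(slice(a, s + a) for (a, _), s in zip(pw, self.shape))
        return Tensor._node(np.pad(self.data, pw), (self,),
                            lambda g: ((self, g[slices]),))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g2, self.shape).copy()),)
        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=True)
        hit = (self.data == data)
        hit = hit / hit.sum(axis=axis, keepdims=True)  # split ties evenly

        def backward(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((self, g2 * hit),)

        out = data if keepdims else data.squeeze(axis)
        return Tensor._node(out, (self,), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,),
                            lambda g: ((self, g * mask),))

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        dens = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return Tensor._node(x * phi, (self,),
                            lambda g: ((self, g * (phi + x * dens)),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._node(t, (self,), lambda g: ((self, g * (1 - t * t)),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._node(e, (self,), lambda g: ((self, g * e),))

    def log(self):
        return Tensor._node(np.log(self.data), (self,),
                            lambda g: ((self, g / self.data),))

    def sqrt(self):
        s = np.sqrt(self.data)
        return Tensor._node(s, (self,), lambda g: ((self, g * 0.5 / s),))

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            out.append((t, g[tuple(sl)]))
        return tuple(out)

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*kh*kw) with zero 'same' padding."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # cols: (N, C, H, W, kh, kw)
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * kh * kw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Same'-padded 2-D convolution (cross-correlation convention).

    ``x`` is (N, C_in, H, W), ``weight`` (C_out, C_in, kh, kw) with odd
    kernel sizes, ``bias`` (C_out,). Implemented as an im2col matmul with
    an explicit col2im backward pass.
    """
    xv, wv = x.data, weight.data
    n, c, h, w = xv.shape
    co, ci, kh, kw = wv.shape
    if ci != c:
        raise ValueError("channel mismatch in conv2d")
    cols = _im2col(xv, kh, kw)                      # (N, HW, C*kh*kw)
    wmat = wv.reshape(co, -1)                       # (C_out, C*kh*kw)
    out = cols @ wmat.T                             # (N, HW, C_out)
    if bias is not None:
        out = out + bias.data
    out = out.transpose(0, 2, 1).reshape(n, co, h, w)

    def backward(g):
        gmat = g.reshape(n, co, h * w).transpose(0, 2, 1)   # (N, HW, C_out)
        gw = np.einsum("npo,npk->ok", gmat, cols).reshape(wv.shape)
        gcols = gmat @ wmat                                  # (N, HW, C*kh*kw)
        gcols = gcols.reshape(n, h, w, c, kh, kw)
        ph, pw = kh // 2, kw // 2
        gx = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
        for di in range(kh):
            for dj in range(kw):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        gx = gx[:, :, ph:ph + h, pw:pw + w]
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, gmat.sum(axis=(0, 1))))
        return tuple(grads)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._node(out, parents, backward)
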