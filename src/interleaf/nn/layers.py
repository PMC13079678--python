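"""Neural building blocks over the autodiff engine.

Modules hold :class:`Parameter` tensors and child modules in their
``__dict__``; :meth:`Module.parameters` walks both. All weight
initialization is driven by an explicit ``numpy.random.Generator``, so a
model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "Conv2d",
           "ChannelMLP", "MultiHeadAttention", "Adam", "concat"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis; weights ~ N(0, 1/fan_in)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        scale = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(scale * rng.standard_normal((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalization over the last axis with learnable gain/offset."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Conv2d(Module):
    """'Same'-padded convolution on (N, C, H, W) tensors."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = in_channels * kernel_size * kernel_size
        scale = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(scale * rng.standard_normal(
            (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ChannelMLP(Module):
    """Two pointwise linear layers with a GELU in between."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiHeadAttention(Module):
    """Scaled dot-product attention over token sequences.

    Accepts (T, d) or batched (..., T, d) inputs; ``kv`` (for
    cross-attention) defaults to the query sequence. An optional boolean
    ``mask`` (T_q, T_kv) marks forbidden key positions.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads = dim, heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def forward(self, x: Tensor, kv: Tensor | None = None,
                mask: np.ndarray | None = None) -> Tensor:
        kv = x if kv is None else kv
        tq, d = x.shape[-2], x.shape[-1]
        tk = kv.shape[-2]
        lead = x.shape[:-2]

        def split(t: Tensor, tlen: int) -> Tensor:
            t = t.reshape(*lead, tlen, self.heads, self.head_dim)
            axes = tuple(range(len(lead))) + (t.ndim - 2, t.ndim - 3, t.ndim - 1)
            return t.transpose(axes)  # (..., heads, T, head_dim)

        q = split(self.wq(x), tq)
        k = split(self.wk(kv), tk)
        v = split(self.wv(kv), tk)
        scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
            * (1.0 / np.sqrt(self.head_dim))
        if mask is not None:
            scores = scores + Tensor(np.where(mask, -1e30, 0.0))
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (..., heads, Tq, head_dim)
        axes = tuple(range(len(lead))) + (out.ndim - 2, out.ndim - 3, out.ndim - 1)
        out = out.transpose(axes).reshape(*lead, tq, d)
        return self.wo(out)

    def attention_weights(self, x: Tensor, kv: Tensor | None = None,
                          mask: np.ndarray | None = None) -> np.ndarray:
        """Attention matrices only (for inspection and tests)."""
        kv = x if kv is None else kv
        tq, tk = x.shape[-2], kv.shape[-2]
        lead = x.shape[:-2]

        def split(t, tlen):
            t = t.reshape(*lead, tlen, self.heads, self.head_dim)
            axes = tuple(range(len(lead))) + (t.ndim - 2, t.ndim - 3, t.ndim - 1)
            return t.transpose(axes)

        q = split(self.wq(x), tq)
        k = split(self.wk(kv), tk)
        scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
            * (1.0 / np.sqrt(self.head_dim))
        if mask is not None:
            scores = scores + Tensor(np.where(mask, -1e30, 0.0))
        return scores.softmax(axis=-1).data


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
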