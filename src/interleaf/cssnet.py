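"""CSSNet: capsule spatial-shift network for hyperspectral classification.

The classifier stacks

1. a convolutional stem (3x3 conv to ``stem_channels``, per-channel
   affine scale/bias, ReLU);
2. residual spatial-shift blocks, P' = P + css(LN(P)) and
   P_out = P' + MLP(LN(P')), where css is the parameter-free four-way
   spatial shift (channel quarters translated one pixel up/down/left/
   right, vacated rows zero-filled) followed by a pointwise channel mix;
3. a hierarchical split/merge cascade of ``n_stages`` stages: stage h
   sums its carried stream with the stage input, applies the spatial
   shift and a pointwise linear map, and splits the result in half along
   channels, one half carried forward and the other emitted; the final
   stage emits unsplit. Emitted halves are channel-concatenated into the
   network's last feature map;
4. a capsule head: channels at each (pooled) spatial site are projected
   and grouped into primary capsule vectors, squashed, and routed by
   agreement into one class capsule per disease class; capsule lengths
   are the class scores.

Outputs per sample are a class probability vector, a severity score
(mean normalized activation over vegetation pixels), and a spatial
activation map (channel mean of the last feature map, min-max
normalized) that the attribution module scores against lesion masks.

Training minimizes a hard-sample top-k loss (cross-entropy restricted to
samples whose true-class score falls below a threshold ``s``) plus an
optional smooth-Dice term aligning the activation map with reference
masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "CSSNetConfig", "Prediction", "LossBreakdown", "ParamReport", "CSSNet",
    "spatial_shift", "squash", "topk_loss", "dice_loss_smooth",
    "param_report", "train", "predict", "features_to_input",
]


def features_to_input(features: np.ndarray, tile: int = 4) -> np.ndarray:
    """Flat-feature mode input: tile each feature over a tile x tile map.

    Turns an (N, F) feature matrix into (N, F, tile, tile) so the same
    spatial-shift architecture (whose shift operator needs spatial
    extent) consumes selected composite features; channel-wise selection
    masks then act on features directly.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None]
    return np.broadcast_to(
        features[:, :, None, None],
        (*features.shape, tile, tile)).copy()

logger = logging.getLogger(__name__)


@dataclass
class CSSNetConfig:
    in_channels: int = 61
    n_classes: int = 16
    stem_channels: int = 16        # L; divisible by 8 (cascade width L/2 shifts)
    n_stages: int = 3              # t, cascade depth (>= 2)
    n_shift_blocks: int = 2
    n_capsules: int = 32
    capsule_dim: int = 16
    routing_iters: int = 3
    pool_to: int = 4               # spatial size entering the capsule head
    topk_threshold: float = 0.9    # s in [0, 1]
    dice_weight: float = 0.0       # beta
    lr: float = 1e-3
    epochs: int = 30
    batch: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.stem_channels % 8:
            raise ValueError("stem_channels must be divisible by 8")
        if self.n_stages < 2:
            raise ValueError("cascade needs at least 2 stages")
        if not 0.0 <= self.topk_threshold <= 1.0:
            raise ValueError("topk_threshold must lie in [0, 1]")


@dataclass
class Prediction:
    class_probs: np.ndarray       # normalized capsule lengths, sums to 1
    raw_lengths: np.ndarray       # squashed class-capsule lengths in [0, 1)
    severity: float
    activation_map: np.ndarray    # H x W in [0, 1]

    @property
    def label(self) -> int:
        return int(np.argmax(self.class_probs))


@dataclass
class LossBreakdown:
    topk: float
    dice: float
    beta: float

    @property
    def total(self) -> float:
        return self.topk + self.beta * self.dice


@dataclass
class ParamReport:
    per_module: dict[str, int]
    closed_form: int
    direct_count: int

    @property
    def consistent(self) -> bool:
        return self.closed_form == self.direct_count


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def spatial_shift(fm: Tensor) -> Tensor:
    """Four-way parameter-free spatial mixing on (..., C, H, W).

    Channels split into four equal groups: group 1 shifts +1 along
    height, group 2 -1 along height, group 3 +1 along width, group 4 -1
    along width; vacated rows/columns are zero-filled. Works on (C, H, W)
    or batched (N, C, H, W) tensors.
    """
    fm = nn.as_tensor(fm)
    squeeze = fm.ndim == 3
    if squeeze:
        fm = fm.reshape(1, *fm.shape)
    n, c, h, w = fm.shape
    if c % 4:
        raise ValueError("channel count must be divisible by 4 for the shift")
    q = c // 4
    zeros2 = ((0, 0), (0, 0))
    g1 = fm[:, 0 * q:1 * q, : h - 1, :].pad(zeros2 + ((1, 0), (0, 0)))
    g2 = fm[:, 1 * q:2 * q, 1:, :].pad(zeros2 + ((0, 1), (0, 0)))
    g3 = fm[:, 2 * q:3 * q, :, : w - 1].pad(zeros2 + ((0, 0), (1, 0)))
    g4 = fm[:, 3 * q:4 * q, :, 1:].pad(zeros2 + ((0, 0), (0, 1)))
    out = nn.concat([g1, g2, g3, g4], axis=1)
    return out.reshape(c, h, w) if squeeze else out


def squash(u: Tensor, axis: int = -1, eps: float = 1e-9) -> Tensor:
    """Capsule nonlinearity v = (|u|^2 / (1 + |u|^2)) * u / |u|."""
    u = nn.as_tensor(u)
    sq = (u * u).sum(axis=axis, keepdims=True)
    norm = (sq + eps).sqrt()
    return u * (sq / (1.0 + sq) / norm)


class _ShiftBlock(nn.Module):
    """Residual spatial-shift mixing block (pre-LN, two branches)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.ln1 = nn.LayerNorm(channels)
        self.mix = nn.Linear(channels, channels, rng)
        self.ln2 = nn.LayerNorm(channels)
        self.mlp = nn.ChannelMLP(channels, 2 * channels, rng)

    @staticmethod
    def _chw_to_sites(x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        return x.transpose(0, 2, 3, 1)

    @staticmethod
    def _sites_to_chw(x: Tensor) -> Tensor:
        return x.transpose(0, 3, 1, 2)

    def forward(self, x: Tensor) -> Tensor:
        # css branch: LN (per site over channels) -> shift -> pointwise mix
        normed = self._sites_to_chw(self.ln1(self._chw_to_sites(x)))
        mixed = self._sites_to_chw(self.mix(self._chw_to_sites(spatial_shift(normed))))
        x = x + mixed
        # channel-MLP branch
        x = x + self._sites_to_chw(self.mlp(self.ln2(self._chw_to_sites(x))))
        return x


class _SplitMergeCascade(nn.Module):
    """Hierarchical split/merge spatial-shift cascade of t stages.

    Stage inputs K_1..K_t are pointwise projections (L -> c = L/2) of the
    incoming map. K_{1,1} = K_1 carries forward. Stage h in [2, t-1]
    computes split(fd_h(shift(K_{h-1,1} + K_h))) with fd_h : c -> 2c,
    carrying the first half and emitting the second; the last stage emits
    fd_t(shift(K_{t-1,1} + K_t)) unsplit (fd_t : c -> c). Emitted maps
    are channel-concatenated: output has (t-1) * c channels.
    """

    def __init__(self, channels: int, t: int, rng: np.random.Generator):
        self.t = t
        self.c = channels // 2
        if self.c % 4:
            raise ValueError("cascade width must be divisible by 4")
        self.stage_proj = [nn.Linear(channels, self.c, rng) for _ in range(t)]
        self.fd_split = [nn.Linear(self.c, 2 * self.c, rng) for _ in range(max(0, t - 2))]
        self.fd_last = nn.Linear(self.c, self.c, rng)

    @staticmethod
    def _pw(linear: nn.Linear, x: Tensor) -> Tensor:
        return linear(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)

    def forward(self, x: Tensor) -> Tensor:
        K = [self._pw(p, x) for p in self.stage_proj]
        carried = K[0]                      # K_{1,1} = K_1
        emitted: list[Tensor] = []
        for h in range(2, self.t + 1):
            merged = spatial_shift(carried + K[h - 1])
            if h < self.t:
                both = self._pw(self.fd_split[h - 2], merged)
                carried = both[:, : self.c]
                emitted.append(both[:, self.c:])
            else:
                emitted.append(self._pw(self.fd_last, merged))
        return nn.concat(emitted, axis=1)


class CSSNet(nn.Module):
    """The full classifier; see the module docstring for the layout."""

    def __init__(self, cfg: CSSNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xC55]))
        L = cfg.stem_channels
        self.stem_conv = nn.Conv2d(cfg.in_channels, L, 3, rng)
        self.stem_scale = nn.Parameter(np.ones(L))     # Z
        self.stem_bias = nn.Parameter(np.zeros(L))     # n
        self.blocks = [_ShiftBlock(L, rng) for _ in range(cfg.n_shift_blocks)]
        self.cascade = _SplitMergeCascade(L, cfg.n_stages, rng)
        feat_channels = (cfg.n_stages - 1) * (L // 2)
        self.caps_proj = nn.Linear(feat_channels,
                                   cfg.n_capsules * cfg.capsule_dim, rng)
        self.routing_W = nn.Parameter(
            (1.0 / np.sqrt(cfg.capsule_dim)) * rng.standard_normal(
                (cfg.n_capsules, cfg.n_classes, cfg.capsule_dim, cfg.capsule_dim)))
        self.cache: dict[str, Tensor] = {}

    # -- pieces ----------------------------------------------------------

    def conv_stem(self, x: Tensor) -> Tensor:
        """F_t = conv3x3(F_in); F_out = relu(Z * F_t + n)."""
        ft = self.stem_conv(x)
        z = self.stem_scale.reshape(1, -1, 1, 1)
        b = self.stem_bias.reshape(1, -1, 1, 1)
        return (ft * z + b).relu()

    def _pool(self, fm: Tensor) -> Tensor:
        n, c, h, w = fm.shape
        p = self.cfg.pool_to
        if h <= p or h % p or w % p:
            return fm
        return (fm.reshape(n, c, p, h // p, p, w // p)
                  .mean(axis=(3, 5)))

    def capsule_head(self, fm: Tensor) -> tuple[Tensor, Tensor]:
        """Primary capsules -> routed class capsules -> squashed lengths."""
        cfg = self.cfg
        pooled = self._pool(fm)
        n, c, h, w = pooled.shape
        sites = pooled.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        prim = self.caps_proj(sites).reshape(
            n, h * w * cfg.n_capsules, cfg.capsule_dim)
        prim = squash(prim, axis=-1)
        # votes: (N, P, D, dim) with weights shared across spatial sites
        prim = prim.reshape(n, h * w, cfg.n_capsules, 1, 1, cfg.capsule_dim)
        u_hat = (prim @ self.routing_W).reshape(
            n, h * w * cfg.n_capsules, cfg.n_classes, cfg.capsule_dim)
        v = self._route(u_hat)
        lengths = ((v * v).sum(axis=-1) + 1e-12).sqrt()   # (N, D)
        return v, lengths

    def _route(self, u_hat: Tensor) -> Tensor:
        """Routing by agreement; coupling softmax over class capsules.

        Votes are aggregated by their coupling-weighted mean (not sum):
        with hundreds of primary capsules a summed vote vector saturates
        the squash for every class, flattening the normalized class
        probabilities and killing the training gradient.
        """
        n, p, d, dim = u_hat.shape
        logits = Tensor(np.zeros((n, p, d, 1)))
        v = None
        for it in range(self.cfg.routing_iters):
            coupling = logits.softmax(axis=2)
            s = (coupling * u_hat).sum(axis=1) * (float(d) / p)   # (N, D, dim)
            v = squash(s, axis=-1)
            if it < self.cfg.routing_iters - 1:
                agree = (u_hat * v.reshape(n, 1, d, dim)).sum(axis=-1, keepdims=True)
                logits = logits + agree
        return v

    # -- forward ---------------------------------------------------------

    def forward(self, x: Tensor | np.ndarray,
                selection_mask: np.ndarray | None = None) -> Tensor:
        """Class-capsule lengths for a batch (N, C, H, W); caches internals.

        ``selection_mask`` (boolean over input channels) zeroes the
        de-selected channels before the stem; a full mask is the identity.
        """
        x = nn.as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if selection_mask is not None:
            keep = np.asarray(selection_mask, dtype=bool)
            if keep.size != x.shape[1]:
                raise ValueError("selection mask length must match input channels")
            if not keep.all():
                x = x * Tensor(keep.astype(float).reshape(1, -1, 1, 1))
        stem = self.conv_stem(x)
        stem.retain_grad = True          # post-ReLU conv layer for Grad-CAM
        fm = stem
        for blk in self.blocks:
            fm = blk(fm)
        fm = self.cascade(fm)
        fm.retain_grad = True
        self.cache = {"stem": stem, "feature_map": fm}
        _, lengths = self.capsule_head(fm)
        self.cache["lengths"] = lengths
        self.cache["activation_map"] = self._activation_map(fm)
        return lengths

    @staticmethod
    def _activation_map(fm: Tensor) -> Tensor:
        amap = fm.mean(axis=1)                       # (N, H, W)
        a = amap.data
        lo = a.min(axis=(1, 2), keepdims=True)
        hi = a.max(axis=(1, 2), keepdims=True)
        span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
        # min/max treated as constants: normalization rescales gradients only
        return (amap - Tensor(lo)) * Tensor(1.0 / span)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def topk_loss(probs: Tensor | np.ndarray, truth: np.ndarray, s: float,
              floor: float = 1e-12) -> Tensor:
    """Hard-sample cross-entropy.

    Over the hard set H = {samples whose true-class score is below ``s``},
    the loss is -mean_H log(score_true); when H is empty it falls back to
    the mean over all samples (keeping gradients alive). Scores are
    floored at ``floor`` inside the log.
    """
    probs = nn.as_tensor(probs)
    truth = np.asarray(truth, dtype=int)
    n = probs.shape[0]
    rows = np.arange(n)
    true_scores = probs[rows, truth]
    hard = true_scores.data < s
    if not hard.any():
        hard = np.ones(n, dtype=bool)
    picked = true_scores[np.flatnonzero(hard)]
    floored = picked + Tensor(np.maximum(floor - picked.data, 0.0))
    return -(floored.log().mean())


def dice_loss_smooth(activation_map: Tensor | np.ndarray,
                     reference_mask: np.ndarray, eps: float = 1.0) -> Tensor:
    """Smooth Dice loss 1 - (2 sum(a*m) + eps) / (sum a + sum m + eps).

    ``activation_map`` holds values in [0, 1]; ``reference_mask`` is
    binary. Batched inputs (N, H, W) are averaged over the batch. The
    eps term keeps the empty/empty case at exactly zero loss.
    """
    a = nn.as_tensor(activation_map)
    m = np.asarray(reference_mask, dtype=float)
    if a.ndim == 2:
        a = a.reshape(1, *a.shape)
        m = m.reshape(1, *m.shape)
    inter = (a * Tensor(m)).sum(axis=(1, 2))
    total = a.sum(axis=(1, 2)) + Tensor(m.sum(axis=(1, 2)))
    dice = (2.0 * inter + eps) / (total + eps)
    return (1.0 - dice).mean()


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def closed_form_param_count(cfg: CSSNetConfig) -> dict[str, int]:
    """Analytic parameter count per module for the concrete architecture.

    Building blocks: a pointwise/dense map a -> b with bias costs
    a*b + b; a 3x3 conv C_in -> C_out with bias costs 9*C_in*C_out +
    C_out; a LayerNorm over C channels costs 2C.
    """
    L = cfg.stem_channels
    c = L // 2
    t = cfg.n_stages
    dense = lambda a, b: a * b + b
    stem = 9 * cfg.in_channels * L + L + 2 * L            # conv + Z + n
    block = (2 * L) + dense(L, L) + (2 * L) + dense(L, 2 * L) + dense(2 * L, L)
    cascade = t * dense(L, c) + max(0, t - 2) * dense(c, 2 * c) + dense(c, c)
    caps = dense((t - 1) * c, cfg.n_capsules * cfg.capsule_dim)
    routing = cfg.n_capsules * cfg.n_classes * cfg.capsule_dim ** 2
    return {"stem": stem, "shift_blocks": cfg.n_shift_blocks * block,
            "cascade": cascade, "capsule_head": caps + routing}


def param_report(model: CSSNet, cfg: CSSNetConfig | None = None) -> ParamReport:
    """Closed-form vs brute-force parameter accounting; must agree exactly."""
    cfg = cfg or model.cfg
    per_module = closed_form_param_count(cfg)
    closed = int(sum(per_module.values()))
    direct = model.n_parameters()
    return ParamReport(per_module=per_module, closed_form=closed,
                       direct_count=direct)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train(model: CSSNet, inputs: np.ndarray, labels: np.ndarray,
          reference_masks: np.ndarray | None = None,
          cfg: CSSNetConfig | None = None,
          selection_mask: np.ndarray | None = None) -> list[float]:
    """Mini-batch training; returns the per-epoch mean total loss.

    ``inputs`` is (N, C, H, W); ``reference_masks`` (N, H, W) supplies the
    Dice reference (lesion masks for diseased samples, vegetation masks
    for healthy ones). When masks are absent the Dice weight is forced to
    zero. Shuffling and initialization derive from ``cfg.seed``, so a run
    is reproducible on a fixed thread count.
    """
    cfg = cfg or model.cfg
    beta = cfg.dice_weight if reference_masks is not None else 0.0
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x7124]))
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    n = len(inputs)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            lengths = model.forward(inputs[idx], selection_mask=selection_mask)
            # normalize lengths into class probabilities: raw capsule
            # lengths admit a degenerate all-high solution (no inter-class
            # competition), so the hard-sample loss acts on the simplex
            probs = lengths / lengths.sum(axis=1, keepdims=True)
            loss = topk_loss(probs, labels[idx], cfg.topk_threshold)
            if beta > 0:
                loss = loss + beta * dice_loss_smooth(
                    model.cache["activation_map"], reference_masks[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += value * len(idx)
        history.append(epoch_loss / n)
        logger.info("epoch %d: loss %.5f", epoch, history[-1])
    return history


def predict(model: CSSNet, inputs: np.ndarray,
            selection_mask: np.ndarray | None = None,
            vegetation_masks: np.ndarray | None = None) -> list[Prediction]:
    """Predictions (probabilities, severity, activation map) per sample."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 3:
        inputs = inputs[None]
    lengths = model.forward(inputs, selection_mask=selection_mask).data
    amaps = model.cache["activation_map"].data
    out = []
    for i in range(len(inputs)):
        raw = lengths[i]
        probs = raw / max(raw.sum(), 1e-12)
        amap = amaps[i]
        if vegetation_masks is not None and vegetation_masks[i].any():
            severity = float(amap[vegetation_masks[i].astype(bool)].mean())
        else:
            severity = float(amap.mean())
        out.append(Prediction(class_probs=probs, raw_lengths=raw,
                              severity=severity, activation_map=amap))
    return out
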