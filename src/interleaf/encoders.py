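"""Spectral-spatial feature extraction: transformer encoders + descriptors.

Four small transformer-style encoders (global-attention ViT, windowed
Swin, pyramidal PVT, and an encoder-decoder DETR variant with learned
queries and no box head) map a hyperspectral patch to fixed-length
embeddings. By default they run in *frozen-random* mode: weights are
drawn once from a seeded generator and never updated, so the encoders act
as deterministic spectral-spatial feature hashers. Every forward pass is
differentiable through the package's autodiff engine, and
:func:`fit_encoder` provides the optional supervised training mode
(a linear probe head trained jointly with the encoder weights).

A complementary set of handcrafted descriptors captures the physiological
signatures used in VNIR plant pathology: red-edge position and shift,
visible chlorophyll-absorption window means, NIR level and variability,
lesion geometry, spatial texture gradient, and inter-band window
correlations. :func:`assemble_features` concatenates everything into a
single vector with a named group-index map, which is both the wrapper
selector's search space and the unit of SHAP attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from skimage.measure import label as cc_label, regionprops

from . import nn
from .cube import BandGrid
from .nn import Tensor

__all__ = [
    "EncoderConfig", "CompositeFeatureVector",
    "ViTEncoder", "SwinEncoder", "PVTEncoder", "DETREncoder", "get_encoder",
    "encode_vit", "encode_swin", "encode_pvt", "encode_detr", "fit_encoder",
    "spectral_descriptors", "lesion_proxy", "red_edge_position",
    "assemble_features", "build_feature_matrix", "DESCRIPTOR_GROUPS",
    "CORR_WINDOWS",
]

# The six fixed wavelength windows whose per-pixel means form the series
# for the inter-band correlation descriptors (and double as physiological
# summary windows).
CORR_WINDOWS: tuple[tuple[float, float], ...] = (
    (450, 500), (540, 580), (550, 600), (600, 650), (680, 740), (720, 980))

DESCRIPTOR_GROUPS = ("red_edge", "chlorophyll_vis", "nir_variation",
                     "lesion_geometry", "texture_gradient", "interband_corr")


@dataclass(frozen=True)
class EncoderConfig:
    """Desk-scale encoder hyperparameters.

    Defaults (embed_dim 32, depth 2, heads 2, 8 queries) are intentionally
    small; the full-scale settings used in the literature (dim 768, depth
    12, 100 queries) are reachable through the same fields.
    """

    name: str = "vit"
    embed_dim: int = 32
    depth: int = 2
    heads: int = 2
    patch_size: int = 16
    window_size: int = 2          # swin, in token units
    stages: int = 2               # pvt
    n_queries: int = 8            # detr
    mlp_ratio: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")


class _Block(nn.Module):
    """Pre-norm transformer block: x + MHSA(LN x), then x + MLP(LN x)."""

    def __init__(self, dim: int, heads: int, mlp_ratio: int,
                 rng: np.random.Generator):
        self.ln1 = nn.LayerNorm(dim)
        self.attn = nn.MultiHeadAttention(dim, heads, rng)
        self.ln2 = nn.LayerNorm(dim)
        self.mlp = nn.ChannelMLP(dim, mlp_ratio * dim, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), mask=mask)
        return x + self.mlp(self.ln2(x))


class _TokenizerMixin:
    def _init_tokenizer(self, cfg: EncoderConfig, patch_shape, rng):
        h, w, b = patch_shape
        ps = cfg.patch_size
        if h % ps or w % ps:
            raise ValueError(f"patch {h}x{w} not divisible by token size {ps}")
        self.grid_hw = (h // ps, w // ps)
        self.proj = nn.Linear(ps * ps * b, cfg.embed_dim, rng)
        n_tok = self.grid_hw[0] * self.grid_hw[1]
        self.pos = nn.Parameter(0.02 * rng.standard_normal((n_tok, cfg.embed_dim)))

    def _tokenize(self, patch: Tensor) -> Tensor:
        h, w, b = patch.shape
        ps = self.cfg.patch_size
        gh, gw = self.grid_hw
        tok = (patch.reshape(gh, ps, gw, ps, b)
                    .transpose(0, 2, 1, 3, 4)
                    .reshape(gh * gw, ps * ps * b))
        return self.proj(tok) + self.pos


class ViTEncoder(nn.Module, _TokenizerMixin):
    """Global self-attention over the token sequence; mean-pooled output."""

    def __init__(self, cfg: EncoderConfig, patch_shape: tuple[int, int, int]):
        self.cfg = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x517]))
        self._init_tokenizer(cfg, patch_shape, rng)
        self.blocks = [_Block(cfg.embed_dim, cfg.heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.depth)]
        self.ln = nn.LayerNorm(cfg.embed_dim)

    def forward(self, patch: Tensor) -> Tensor:
        x = self._tokenize(patch)
        for blk in self.blocks:
            x = blk(x)
        return self.ln(x).mean(axis=0)


class SwinEncoder(nn.Module, _TokenizerMixin):
    """Windowed self-attention with alternating shifted windows.

    Unshifted layers attend strictly within ``window_size`` x
    ``window_size`` token tiles; every second layer cyclically rolls the
    token grid by half a window before the windowed attention, letting
    information cross tile boundaries. When the window covers the whole
    grid the shift is disabled and the layer is exactly global attention.
    """

    def __init__(self, cfg: EncoderConfig, patch_shape: tuple[int, int, int]):
        self.cfg = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x5177]))
        self._init_tokenizer(cfg, patch_shape, rng)
        gh, gw = self.grid_hw
        ws = cfg.window_size
        if gh % ws or gw % ws:
            raise ValueError("token grid must be divisible by window_size")
        self.blocks = [_Block(cfg.embed_dim, cfg.heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.depth)]
        self.ln = nn.LayerNorm(cfg.embed_dim)

    def _window_attn(self, x: Tensor, blk: _Block, shift: int) -> Tensor:
        gh, gw = self.grid_hw
        ws = self.cfg.window_size
        d = self.cfg.embed_dim
        grid = x.reshape(gh, gw, d)
        if shift:
            rolled = np.roll(np.arange(gh * gw).reshape(gh, gw), (-shift, -shift),
                             axis=(0, 1)).ravel()
            grid = x[rolled].reshape(gh, gw, d)
        windows = (grid.reshape(gh // ws, ws, gw // ws, ws, d)
                       .transpose(0, 2, 1, 3, 4)
                       .reshape((gh // ws) * (gw // ws), ws * ws, d))
        out = blk(windows)
        out = (out.reshape(gh // ws, gw // ws, ws, ws, d)
                  .transpose(0, 2, 1, 3, 4)
                  .reshape(gh * gw, d))
        if shift:
            unrolled = np.empty(gh * gw, dtype=int)
            unrolled[rolled] = np.arange(gh * gw)
            out = out[unrolled]
        return out

    def forward(self, patch: Tensor) -> Tensor:
        x = self._tokenize(patch)
        gh, gw = self.grid_hw
        ws = self.cfg.window_size
        for i, blk in enumerate(self.blocks):
            shift = ws // 2 if (i % 2 == 1 and ws < min(gh, gw)) else 0
            x = self._window_attn(x, blk, shift)
        return self.ln(x).mean(axis=0)


class PVTEncoder(nn.Module, _TokenizerMixin):
    """Pyramidal encoder: attention stages separated by 2x2 patch merging."""

    def __init__(self, cfg: EncoderConfig, patch_shape: tuple[int, int, int]):
        self.cfg = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x9F7]))
        self._init_tokenizer(cfg, patch_shape, rng)
        gh, gw = self.grid_hw
        if cfg.stages < 1:
            raise ValueError("need at least one stage")
        if gh % 2 ** (cfg.stages - 1) or gw % 2 ** (cfg.stages - 1):
            raise ValueError("token grid must survive the stage-wise halving")
        d = cfg.embed_dim
        self.blocks = [_Block(d, cfg.heads, cfg.mlp_ratio, rng)
                       for _ in range(cfg.stages * max(1, cfg.depth // cfg.stages))]
        self.merges = [nn.Linear(4 * d, d, rng) for _ in range(cfg.stages - 1)]
        self.ln = nn.LayerNorm(d)
        self.blocks_per_stage = max(1, cfg.depth // cfg.stages)

    def forward(self, patch: Tensor) -> Tensor:
        x = self._tokenize(patch)
        gh, gw = self.grid_hw
        d = self.cfg.embed_dim
        bi = 0
        for stage in range(self.cfg.stages):
            for _ in range(self.blocks_per_stage):
                x = self.blocks[bi](x)
                bi += 1
            if stage < self.cfg.stages - 1:
                x = (x.reshape(gh // 2, 2, gw // 2, 2, d)
                      .transpose(0, 2, 1, 3, 4)
                      .reshape((gh // 2) * (gw // 2), 4 * d))
                x = self.merges[stage](x)
                gh, gw = gh // 2, gw // 2
        return self.ln(x).mean(axis=0)


class DETREncoder(nn.Module, _TokenizerMixin):
    """Encoder-decoder feature extractor with learned object queries.

    The transformer encoder contextualizes the token sequence; a decoder
    of ``n_queries`` learned queries self-attends and cross-attends to the
    encoder output. Decoder outputs are mean-pooled into the embedding;
    no bounding-box head exists.
    """

    def __init__(self, cfg: EncoderConfig, patch_shape: tuple[int, int, int]):
        self.cfg = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xDE7]))
        self._init_tokenizer(cfg, patch_shape, rng)
        d = cfg.embed_dim
        self.enc_blocks = [_Block(d, cfg.heads, cfg.mlp_ratio, rng)
                           for _ in range(cfg.depth)]
        self.queries = nn.Parameter(0.02 * rng.standard_normal((cfg.n_queries, d)))
        self.dec_self = [_Block(d, cfg.heads, cfg.mlp_ratio, rng)
                         for _ in range(cfg.depth)]
        self.dec_cross_ln = [nn.LayerNorm(d) for _ in range(cfg.depth)]
        self.dec_cross = [nn.MultiHeadAttention(d, cfg.heads, rng)
                          for _ in range(cfg.depth)]
        self.ln = nn.LayerNorm(d)

    def forward(self, patch: Tensor) -> Tensor:
        mem = self._tokenize(patch)
        for blk in self.enc_blocks:
            mem = blk(mem)
        q = self.queries
        for sa, ln, ca in zip(self.dec_self, self.dec_cross_ln, self.dec_cross):
            q = sa(q)
            q = q + ca(ln(q), kv=mem)
        return self.ln(q).mean(axis=0)


_ENCODER_CLASSES = {"vit": ViTEncoder, "swin": SwinEncoder,
                    "pvt": PVTEncoder, "detr": DETREncoder}


@lru_cache(maxsize=32)
def _cached_encoder(cfg: EncoderConfig, patch_shape: tuple[int, int, int]):
    return _ENCODER_CLASSES[cfg.name](cfg, patch_shape)


def get_encoder(cfg: EncoderConfig, patch_shape: tuple[int, int, int]) -> nn.Module:
    """Encoder instance for ``cfg`` (cached; frozen-random weights)."""
    if cfg.name not in _ENCODER_CLASSES:
        raise ValueError(f"unknown encoder '{cfg.name}'")
    return _cached_encoder(cfg, tuple(int(s) for s in patch_shape))


def _encode(name: str, patch: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    cfg = replace(cfg, name=name)
    enc = get_encoder(cfg, patch.shape)
    return enc(Tensor(np.asarray(patch, dtype=float))).data


def encode_vit(patch: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """Frozen-random ViT embedding of one H x W x B patch."""
    return _encode("vit", patch, cfg)


def encode_swin(patch: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    return _encode("swin", patch, cfg)


def encode_pvt(patch: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    return _encode("pvt", patch, cfg)


def encode_detr(patch: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    return _encode("detr", patch, cfg)


def fit_encoder(encoder: nn.Module, patches: np.ndarray, labels: np.ndarray,
                n_classes: int, epochs: int = 10, lr: float = 1e-3,
                seed: int = 0) -> nn.Module:
    """Optional joint-training mode: tune encoder weights supervised.

    Attaches a linear probe head to the pooled embedding and minimizes
    cross-entropy over ``epochs`` full passes, updating encoder and head
    jointly. Returns the encoder (trained in place).
    """
    rng = np.random.default_rng(seed)
    dim = encoder.cfg.embed_dim
    head = nn.Linear(dim, n_classes, rng)
    opt = nn.Adam(encoder.parameters() + head.parameters(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(len(patches))
        for i in order:
            emb = encoder(Tensor(patches[i])).reshape(1, -1)
            logits = head(emb)
            logp = (logits.softmax(axis=-1) + 1e-12).log()
            loss = -logp[0, int(labels[i])]
            opt.zero_grad()
            loss.backward()
            opt.step()
    return encoder


# ---------------------------------------------------------------------------
# handcrafted spectral descriptors
# ---------------------------------------------------------------------------

def red_edge_position(spectrum: np.ndarray, grid: BandGrid,
                      low_nm: float = 690.0, high_nm: float = 750.0) -> float:
    """Wavelength of maximum spectral slope in the red-edge region.

    The derivative maximum is refined by parabolic interpolation through
    the peak and its neighbours, giving sub-band resolution (the red-edge
    inflection shifts by only a few nm under stress, well below typical
    band spacing).
    """
    sel = grid.band_slice(low_nm, high_nm)
    lam = grid.wavelengths_nm
    deriv = np.gradient(spectrum, lam)
    idx = np.flatnonzero(sel)
    k = idx[np.argmax(deriv[idx])]
    if 0 < k < lam.size - 1:
        y0, y1, y2 = deriv[k - 1], deriv[k], deriv[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-15:
            offset = np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0)
            return float(lam[k] + offset * 0.5 * (lam[min(k + 1, lam.size - 1)]
                                                  - lam[max(k - 1, 0)]))
    return float(lam[k])


def lesion_proxy(patch: np.ndarray, grid: BandGrid, k: float = 2.5) -> np.ndarray:
    """Proxy lesion mask from red-edge anomaly on vegetation pixels.

    Vegetation pixels are NDVI > 0.35 (bands nearest 670/800 nm). Within
    them, the red-edge normalized difference (NIR - RE)/(NIR + RE) with
    RE the 700-749 nm window mean and NIR the 780-980 nm window mean is
    computed per pixel; pixels deviating from the leaf median by more
    than ``k`` robust standard deviations (1.4826 x MAD) in either
    direction are flagged. Disease signatures perturb some part of the
    red-edge region, which this contrast responds to regardless of the
    sign of the reflectance change.
    """
    red = patch[:, :, grid.index_of(670.0)]
    nir800 = patch[:, :, grid.index_of(800.0)]
    ndvi = (nir800 - red) / (nir800 + red + 1e-8)
    leaf = ndvi > 0.35
    if leaf.sum() < 8:
        return np.zeros_like(leaf)
    re = patch[:, :, grid.band_slice(700, 749)].mean(axis=2)
    nir = patch[:, :, grid.band_slice(780, 980)].mean(axis=2)
    rend = (nir - re) / (nir + re + 1e-8)
    vals = rend[leaf]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    sd = 1.4826 * mad + 1e-9
    return leaf & (np.abs(rend - med) > k * sd)


def spectral_descriptors(patch: np.ndarray, grid: BandGrid,
                         lesion_proxy_mask: np.ndarray | None = None,
                         healthy_red_edge_nm: float = 715.0
                         ) -> dict[str, np.ndarray]:
    """Named handcrafted descriptor groups for one H x W x B patch.

    Window descriptors are computed over vegetation pixels only (NDVI >
    0.35; the whole patch if too few qualify) and, except for the NIR
    group, on NIR-normalized spectra (each pixel divided by its 780-980
    nm mean). Soil pixels would otherwise dilute the leaf signal, and the
    band-ratio form cancels the multiplicative illumination field, the
    dominant nuisance in field imagery.

    Groups (in canonical order):

    - ``red_edge``: red-edge position (nm) of the leaf-mean spectrum and
      its shift against a healthy reference position;
    - ``chlorophyll_vis``: normalized means over 450-500, 540-600 and
      600-650 nm (the chlorophyll-sensitive 450-650 nm visible range);
    - ``nir_variation``: raw-reflectance mean and sd in 720-980 nm;
    - ``lesion_geometry``: area fraction, blob count and mean eccentricity
      of the (proxy) lesion mask;
    - ``texture_gradient``: mean spatial gradient magnitude of the NIR band;
    - ``interband_corr``: upper-triangle correlations between the six
      fixed window-mean series of :data:`CORR_WINDOWS`.
    """
    patch = np.asarray(patch, dtype=float)
    red = patch[:, :, grid.index_of(670.0)]
    nir800 = patch[:, :, grid.index_of(800.0)]
    ndvi = (nir800 - red) / (nir800 + red + 1e-8)
    leaf = ndvi > 0.35
    if leaf.sum() < 8:
        leaf = np.ones_like(leaf)
    leaf_px = patch[leaf]                                    # (n_leaf, B)
    nir_level = leaf_px[:, grid.band_slice(780, 980)].mean(axis=1, keepdims=True)
    normed = leaf_px / np.maximum(nir_level, 1e-8)

    pos = red_edge_position(leaf_px.mean(axis=0), grid)
    red_edge = np.array([pos, pos - healthy_red_edge_nm])

    def wmean(low, high, source=normed):
        return source[:, grid.band_slice(low, high)].mean(axis=1)

    chlorophyll_vis = np.array([wmean(450, 500).mean(),
                                wmean(540, 600).mean(),
                                wmean(600, 650).mean()])
    nir = wmean(720, 980, source=leaf_px)
    nir_variation = np.array([nir.mean(), nir.std()])

    if lesion_proxy_mask is None:
        lesion_proxy_mask = lesion_proxy(patch, grid)
    area_fraction = float(lesion_proxy_mask.mean())
    labelled = cc_label(lesion_proxy_mask)
    props = regionprops(labelled)
    blob_count = float(len(props))
    ecc = float(np.mean([p.eccentricity for p in props])) if props else 0.0
    lesion_geometry = np.array([area_fraction, blob_count, ecc])

    nir_band = patch[:, :, grid.index_of(800.0)]
    gy, gx = np.gradient(nir_band)
    texture_gradient = np.array([float(np.hypot(gy, gx).mean())])

    series = np.stack([wmean(lo, hi) for lo, hi in CORR_WINDOWS])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(series)
    corr = np.nan_to_num(corr, nan=0.0)
    iu = np.triu_indices(len(CORR_WINDOWS), k=1)
    interband_corr = corr[iu]

    return {"red_edge": red_edge, "chlorophyll_vis": chlorophyll_vis,
            "nir_variation": nir_variation, "lesion_geometry": lesion_geometry,
            "texture_gradient": texture_gradient, "interband_corr": interband_corr}


# ---------------------------------------------------------------------------
# composite feature vector
# ---------------------------------------------------------------------------

@dataclass
class CompositeFeatureVector:
    """Flat feature vector plus a named map of contiguous index ranges."""

    values: np.ndarray
    group_map: dict[str, tuple[int, int]]

    def __post_init__(self):
        edges = sorted(self.group_map.values())
        cursor = 0
        for lo, hi in edges:
            if lo != cursor or hi <= lo:
                raise ValueError("group ranges must partition [0, L) exactly once")
            cursor = hi
        if cursor != self.values.size:
            raise ValueError("group ranges must cover the full vector")

    def group(self, name: str) -> np.ndarray:
        lo, hi = self.group_map[name]
        return self.values[lo:hi]


EMBED_GROUPS = ("vit_embed", "swin_embed", "pvt_embed", "detr_embed")


def assemble_features(embeddings: dict[str, np.ndarray],
                      descriptors: dict[str, np.ndarray]
                      ) -> CompositeFeatureVector:
    """Concatenate encoder embeddings and descriptor groups, in fixed order."""
    parts: list[np.ndarray] = []
    group_map: dict[str, tuple[int, int]] = {}
    cursor = 0
    for name in EMBED_GROUPS:
        key = name if name in embeddings else name.removesuffix("_embed")
        if key not in embeddings:
            continue
        vec = np.asarray(embeddings[key]).ravel()
        group_map[name] = (cursor, cursor + vec.size)
        cursor += vec.size
        parts.append(vec)
    for name in DESCRIPTOR_GROUPS:
        if name in descriptors:
            vec = np.asarray(descriptors[name]).ravel()
            group_map[name] = (cursor, cursor + vec.size)
            cursor += vec.size
            parts.append(vec)
    values = np.concatenate(parts) if parts else np.empty(0)
    return CompositeFeatureVector(values=values, group_map=group_map)


def build_feature_matrix(patches: np.ndarray, grid: BandGrid,
                         cfg: EncoderConfig | None = None,
                         encoder_names: tuple[str, ...] = ("vit", "swin", "pvt", "detr"),
                         healthy_red_edge_nm: float = 715.0
                         ) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Composite feature matrix for a stack of patches (n, H, W, B)."""
    cfg = cfg or EncoderConfig()
    rows = []
    group_map = None
    for patch in patches:
        emb = {name: _encode(name, patch, cfg) for name in encoder_names}
        desc = spectral_descriptors(patch, grid,
                                    healthy_red_edge_nm=healthy_red_edge_nm)
        cfv = assemble_features(emb, desc)
        rows.append(cfv.values)
        group_map = cfv.group_map
    return np.vstack(rows), group_map
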