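"""Model interpretability: Grad-CAM, LIME-style local surrogates, KernelSHAP.

Three complementary views of what drives a CSSNet prediction:

- :func:`grad_cam` backpropagates a class score to the network's last
  spatial feature map, pools the gradients channel-wise into weights and
  forms a ReLU-rectified weighted activation sum — a class-specific
  localization map that :func:`cam_dice` scores against ground-truth
  lesion masks (available here because the synthetic scenes carry them).
- :func:`lime_explain` fits a weighted ridge surrogate to the model's
  responses on randomly perturbed copies of one scene, where the
  interpretable components are spectral windows crossed with spatial
  quadrants and switched-off components are replaced by training-mean
  reflectance.
- :func:`kernel_shap` estimates Shapley values of the composite feature
  groups by the Shapley-kernel weighted least squares, with the
  efficiency constraint (attributions sum to the prediction minus the
  baseline) enforced exactly; with few groups the coalition enumeration
  is exhaustive and the estimate equals the exact Shapley value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import comb

import numpy as np
from sklearn.linear_model import Ridge

from .cube import BandGrid
from .cssnet import CSSNet

__all__ = [
    "CamMap", "LocalExplanation", "ShapAttribution",
    "grad_cam", "cam_dice", "lime_explain", "kernel_shap", "shap_summary",
    "LIME_WINDOWS",
]

# Disjoint spectral windows (nm) whose edges follow the key-wavelength
# breakpoints of the crop-disease classes; crossed with spatial quadrants
# they form the LIME perturbation components.
LIME_WINDOWS: tuple[tuple[float, float], ...] = (
    (400, 450), (450, 500), (500, 540), (540, 580), (580, 620),
    (620, 680), (680, 700), (700, 740), (740, 780), (780, 1000))


@dataclass
class CamMap:
    map: np.ndarray
    target_class: int
    layer_name: str


@dataclass
class LocalExplanation:
    weights: dict[str, float]
    intercept: float
    fidelity_r2: float
    n_perturbations: int

    def top(self, k: int = 5) -> list[tuple[str, float]]:
        return sorted(self.weights.items(), key=lambda kv: -abs(kv[1]))[:k]


@dataclass
class ShapAttribution:
    phi: dict[str, float]
    base_value: float
    model_output: float

    @property
    def efficiency_gap(self) -> float:
        return abs(sum(self.phi.values()) + self.base_value - self.model_output)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def _bilinear_resize2d(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Align-corners bilinear resize of a 2-D map."""
    h, w = arr.shape
    if (h, w) == (out_h, out_w):
        return arr.copy()
    ys = np.linspace(0, h - 1, out_h)
    xs = np.linspace(0, w - 1, out_w)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 2) if h > 1 else np.zeros(out_h, int)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 2) if w > 1 else np.zeros(out_w, int)
    fy = (ys - y0)[:, None] if h > 1 else np.zeros((out_h, 1))
    fx = (xs - x0)[None, :] if w > 1 else np.zeros((1, out_w))
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    top = arr[y0][:, x0] * (1 - fx) + arr[y0][:, x1] * fx
    bot = arr[y1][:, x0] * (1 - fx) + arr[y1][:, x1] * fx
    return top * (1 - fy) + bot * fy


def grad_cam(model: CSSNet, x: np.ndarray, class_id: int,
             layer: str = "feature_map",
             selection_mask: np.ndarray | None = None) -> CamMap:
    """Class activation map from gradients at the last spatial feature map.

    The class score (the raw capsule length of ``class_id``; the
    normalized probability saturates for confidently classified samples
    and its gradient vanishes) is backpropagated to the chosen cached
    layer; per-channel weights are the spatial means of those gradients,
    and the map is ReLU(sum_c w_c A_c), min-max normalized and bilinearly
    upsampled to the input spatial size.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[None]
    lengths = model.forward(x, selection_mask=selection_mask)
    if layer not in model.cache:
        raise ValueError(f"unknown layer '{layer}'")
    fm = model.cache[layer]
    if fm.ndim != 4 or fm.shape[2] < 2 or fm.shape[3] < 2:
        raise ValueError(f"layer '{layer}' has no usable spatial extent")
    score = lengths[:, class_id].sum()
    fm.grad = None
    score.backward()
    grads = fm.grad                                   # (N, C, H', W')
    weights = grads.mean(axis=(2, 3))                 # (N, C)
    cam = np.maximum((weights[:, :, None, None] * fm.data).sum(axis=1), 0.0)
    lo = cam.min(axis=(1, 2), keepdims=True)
    hi = cam.max(axis=(1, 2), keepdims=True)
    span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
    cam = (cam - lo) / span
    out = _bilinear_resize2d(cam[0], x.shape[2], x.shape[3])
    return CamMap(map=out, target_class=int(class_id), layer_name=layer)


def cam_dice(cam: CamMap | np.ndarray, lesion_mask: np.ndarray,
             threshold: float = 0.5) -> float:
    """Dice overlap of the thresholded activation map with a binary mask.

    2|A n M| / (|A| + |M|); both empty counts as perfect agreement (1).
    """
    arr = cam.map if isinstance(cam, CamMap) else np.asarray(cam)
    a = arr >= threshold
    m = np.asarray(lesion_mask, dtype=bool)
    denom = a.sum() + m.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & m).sum() / denom)


# ---------------------------------------------------------------------------
# LIME
# ---------------------------------------------------------------------------

def _quadrants(h: int, w: int, n: int = 2) -> list[tuple[slice, slice]]:
    hs = np.linspace(0, h, n + 1).astype(int)
    ws = np.linspace(0, w, n + 1).astype(int)
    return [(slice(hs[i], hs[i + 1]), slice(ws[j], ws[j + 1]))
            for i in range(n) for j in range(n)]


def lime_explain(model_fn, instance: np.ndarray, grid: BandGrid,
                 train_mean: np.ndarray, n_perturb: int = 500,
                 kernel_width: float = 0.25, n_spatial: int = 2,
                 windows: tuple[tuple[float, float], ...] = LIME_WINDOWS,
                 seed: int = 0) -> LocalExplanation:
    """Local surrogate over spectral-window x spatial-quadrant components.

    ``model_fn`` maps an H x W x B cube to a scalar (e.g. the probability
    of the predicted class); ``train_mean`` is the per-band training-mean
    spectrum used as the switched-off replacement (zeros would be far out
    of distribution for reflectance data). ``n_perturb`` random on/off
    component patterns (the first is all-on) are scored, weighted by
    exp(-d^2 / kernel_width^2) with d the fraction of switched-off
    components, and a ridge surrogate is fitted; its weighted R^2 on the
    perturbation set is reported as fidelity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x117E]))
    instance = np.asarray(instance, dtype=float)
    h, w, b = instance.shape
    quads = _quadrants(h, w, n_spatial)
    names = []
    usable = []
    for wi, (lo, hi) in enumerate(windows):
        sel = (grid.wavelengths_nm >= lo) & (grid.wavelengths_nm < hi)
        if not sel.any():
            continue
        for qi in range(len(quads)):
            usable.append((sel, qi))
            names.append(f"{int(lo)}-{int(hi)}nm:q{qi}")
    k = len(usable)

    Z = rng.integers(0, 2, size=(n_perturb, k)).astype(bool)
    Z[0] = True
    responses = np.empty(n_perturb)
    for r in range(n_perturb):
        if Z[r].all():
            pert = instance
        else:
            pert = instance.copy()
            for ci in np.flatnonzero(~Z[r]):
                sel, qi = usable[ci]
                ys, xs = quads[qi]
                pert[ys, xs, sel] = train_mean[sel]
        responses[r] = model_fn(pert)

    d = 1.0 - Z.mean(axis=1)
    sample_weight = np.exp(-(d**2) / kernel_width**2)
    ridge = Ridge(alpha=1.0)
    ridge.fit(Z.astype(float), responses, sample_weight=sample_weight)
    pred = ridge.predict(Z.astype(float))
    resid = np.average((responses - pred) ** 2, weights=sample_weight)
    total = np.average(
        (responses - np.average(responses, weights=sample_weight)) ** 2,
        weights=sample_weight)
    r2 = 1.0 - resid / total if total > 0 else 1.0
    return LocalExplanation(
        weights=dict(zip(names, ridge.coef_.tolist())),
        intercept=float(ridge.intercept_), fidelity_r2=float(r2),
        n_perturbations=n_perturb)


# ---------------------------------------------------------------------------
# KernelSHAP
# ---------------------------------------------------------------------------

def kernel_shap(model_fn, instance: np.ndarray, background: np.ndarray,
                groups: dict[str, tuple[int, int]],
                n_coalitions: int | None = None, seed: int = 0
                ) -> ShapAttribution:
    """Shapley attributions of feature groups by weighted least squares.

    ``model_fn`` maps a flat feature vector to a scalar; ``background``
    is the replacement vector (training mean) substituted into the
    positions of switched-off groups. When the number of groups G allows
    it (2^G <= n_coalitions, or n_coalitions is None), every coalition is
    enumerated and the solution is the exact Shapley value; otherwise
    coalitions are sampled from the Shapley-kernel distribution. The
    efficiency constraint sum(phi) = f(x) - f(background) is enforced by
    substitution, so it holds to solver precision on every call.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x54A9]))
    instance = np.asarray(instance, dtype=float)
    background = np.asarray(background, dtype=float)
    names = list(groups)
    G = len(names)
    if G < 2:
        raise ValueError("need at least two groups")

    def value(z: np.ndarray) -> float:
        x = background.copy()
        for gi, on in enumerate(z):
            if on:
                lo, hi = groups[names[gi]]
                x[lo:hi] = instance[lo:hi]
        return float(model_fn(x))

    v0 = value(np.zeros(G, dtype=bool))
    v1 = value(np.ones(G, dtype=bool))

    exhaustive = n_coalitions is None or 2**G - 2 <= n_coalitions
    if exhaustive:
        zs = [np.array(bits, dtype=bool)
              for bits in product((0, 1), repeat=G)
              if 0 < sum(bits) < G]
    else:
        sizes = np.arange(1, G)
        size_w = (G - 1) / (sizes * (G - sizes))
        size_w = size_w / size_w.sum()
        zs = []
        for _ in range(n_coalitions):
            k = rng.choice(sizes, p=size_w)
            z = np.zeros(G, dtype=bool)
            z[rng.choice(G, size=k, replace=False)] = True
            zs.append(z)

    Zm = np.array(zs, dtype=float)
    vv = np.array([value(z) for z in zs])
    ks = Zm.sum(axis=1).astype(int)
    wgt = np.array([(G - 1) / (comb(G, k) * k * (G - k)) for k in ks])

    # eliminate phi_G via efficiency: phi_G = (v1 - v0) - sum_{j<G} phi_j
    A = Zm[:, :-1] - Zm[:, -1:]
    y = vv - v0 - Zm[:, -1] * (v1 - v0)
    sw = np.sqrt(wgt)
    phi_head, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    phi = np.append(phi_head, (v1 - v0) - phi_head.sum())
    return ShapAttribution(phi=dict(zip(names, phi.tolist())),
                           base_value=v0, model_output=v1)


def shap_summary(attributions: list[ShapAttribution]):
    """Groups ranked by mean absolute attribution across instances."""
    import pandas as pd

    names = list(attributions[0].phi)
    mat = np.array([[a.phi[n] for n in names] for a in attributions])
    df = pd.DataFrame({
        "group": names,
        "mean_abs_phi": np.abs(mat).mean(axis=0),
        "mean_phi": mat.mean(axis=0),
    }).sort_values("mean_abs_phi", ascending=False).reset_index(drop=True)
    return df
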