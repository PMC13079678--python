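"""Synthetic hyperspectral leaf-disease scene and benchmark generator.

The simulator emulates the statistical structure that the detection
pipeline assumes of VNIR (400-1000 nm) leaf imagery from intercropped
fields: a smooth vegetation reflectance curve with chlorophyll absorption
dips near 450-500 nm and 680 nm and a red-edge rise to an NIR plateau; a
flat low-NIR soil background (NDVI well below the 0.35 vegetation
threshold); per-class disease signatures expressed as signed relative
reflectance deviations confined to class-specific key wavelength windows;
lesions as disc-union blobs on the leaf; band-correlated sensor noise and
a smooth multiplicative illumination field.

Everything is deterministic given a master seed: per-sample seeds are
derived through ``numpy.random.SeedSequence`` keyed on
(master seed, class id, split id, index), so splits are independent
streams and regenerating any single sample never requires generating the
rest of the dataset.

A separate tabular generator (:func:`simulate_feature_benchmark`) builds
labelled feature matrices with known informative / redundant / noise
columns, used to exercise the wrapper feature selector in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .cube import BandGrid, ReflectanceCube, default_grid

__all__ = [
    "ClassSpec",
    "SyntheticSample",
    "FeatureBenchmark",
    "make_class_signature",
    "healthy_baseline",
    "soil_signature",
    "simulate_cube",
    "simulate_dataset",
    "plan_dataset",
    "simulate_feature_benchmark",
    "table2_specs",
    "SPLITS",
]

SPLITS = ("train", "val", "test")

# Per-crop baseline curve parameters: (NIR plateau height, green-peak
# amplitude, red-edge inflection wavelength nm). Crops differ in canopy
# structure and chlorophyll content, which the simulator expresses as
# distinct plateau/peak/edge parameters so that healthy classes of
# different crops are spectrally separable.
CROP_BASELINES: dict[str, tuple[float, float, float]] = {
    "maize": (0.52, 0.068, 716.0),
    "soybean": (0.46, 0.080, 712.0),
    "pea": (0.58, 0.128, 720.0),
    "cucumber": (0.38, 0.040, 708.0),
}
_DEFAULT_BASELINE = (0.48, 0.075, 714.0)


@dataclass(frozen=True)
class ClassSpec:
    """One crop-disease class: its spectral deviation and lesion statistics.

    ``reflectance_delta`` is the signed relative reflectance change applied
    (with a raised-cosine taper) inside each entry of ``key_windows``;
    ``lesion_density`` is the expected lesion count per leaf (Poisson).
    Healthy classes carry ``reflectance_delta = 0`` and zero density.
    ``counts`` are (train, val, test) sample counts.
    """

    crop: str
    disease: str
    key_windows: tuple[tuple[float, float], ...] = ()
    reflectance_delta: float = 0.0
    lesion_density: float = 0.0
    counts: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError("sample counts must be non-negative")
        for low, high in self.key_windows:
            if not low < high:
                raise ValueError(f"empty key window ({low}, {high})")
        if self.is_healthy and self.lesion_density != 0:
            raise ValueError("healthy classes must have lesion_density = 0")

    @property
    def is_healthy(self) -> bool:
        return self.reflectance_delta == 0.0 or not self.key_windows

    @property
    def name(self) -> str:
        return f"{self.crop}/{self.disease}"


class SyntheticSample:
    """A simulated scene: cube + label + ground-truth masks + provenance.

    The raster payload is generated lazily on first access so that
    dataset-level bookkeeping (counts, splits, manifests) costs nothing;
    the same seed always regenerates the identical sample.
    """

    def __init__(self, spec: ClassSpec, label: int, split: str, seed: int,
                 grid: BandGrid, height: int, width: int, params: dict | None = None):
        self.spec = spec
        self.label = int(label)
        self.split = split
        self.seed = int(seed)
        self.grid = grid
        self.height = int(height)
        self.width = int(width)
        self.params = dict(params or {})
        self._payload: tuple[ReflectanceCube, np.ndarray, np.ndarray] | None = None

    def _materialize(self):
        if self._payload is None:
            full = simulate_cube(self.spec, self.grid, self.height, self.width,
                                 self.seed, **self.params, _label=self.label,
                                 _split=self.split)
            self._payload = (full.cube, full.lesion_mask, full.leaf_mask)
        return self._payload

    @property
    def cube(self) -> ReflectanceCube:
        return self._materialize()[0]

    @property
    def lesion_mask(self) -> np.ndarray:
        return self._materialize()[1]

    @property
    def leaf_mask(self) -> np.ndarray:
        return self._materialize()[2]


@dataclass
class FeatureBenchmark:
    """Tabular benchmark with known-relevant features.

    ``informative_idx``, ``redundant_idx`` and ``noise_idx`` partition the
    feature axis: class information enters only through the informative
    columns (and linearly through the redundant ones).
    """

    X: np.ndarray
    y: np.ndarray
    informative_idx: np.ndarray
    redundant_idx: np.ndarray
    noise_idx: np.ndarray

    def __post_init__(self):
        all_idx = np.sort(np.concatenate(
            [self.informative_idx, self.redundant_idx, self.noise_idx]))
        if not np.array_equal(all_idx, np.arange(self.X.shape[1])):
            raise ValueError("index sets must partition the feature axis")


# ---------------------------------------------------------------------------
# spectral signatures
# ---------------------------------------------------------------------------

def healthy_baseline(crop: str, grid: BandGrid, seed: int = 0,
                     jitter: float = 0.01) -> np.ndarray:
    """Smooth parametric vegetation reflectance curve for one crop.

    R(lambda) = floor
                + green_amp * exp(-(lambda-550)^2 / (2*25^2))     green peak
                - 0.015    * exp(-(lambda-480)^2 / (2*20^2))      blue dip
                - 0.020    * exp(-(lambda-680)^2 / (2*12^2))      red dip
                + plateau  / (1 + exp(-(lambda-edge)/10))         red edge -> NIR

    with mild multiplicative leaf-to-leaf jitter (sd ``jitter``) on the
    plateau and peak amplitudes, drawn deterministically from ``seed``.
    """
    plateau, green_amp, edge = CROP_BASELINES.get(crop, _DEFAULT_BASELINE)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xB45E]))
    plateau = plateau * (1.0 + jitter * rng.standard_normal())
    green_amp = green_amp * (1.0 + jitter * rng.standard_normal())
    lam = grid.wavelengths_nm
    curve = (
        0.04
        + green_amp * np.exp(-((lam - 550.0) ** 2) / (2 * 25.0**2))
        - 0.015 * np.exp(-((lam - 480.0) ** 2) / (2 * 20.0**2))
        - 0.020 * np.exp(-((lam - 680.0) ** 2) / (2 * 12.0**2))
        + plateau / (1.0 + np.exp(-(lam - edge) / 10.0))
    )
    return np.clip(curve, 0.005, 1.2)


def _window_taper(lam: np.ndarray, low: float, high: float) -> np.ndarray:
    """Raised-cosine taper: 1 at the window center, 0 at and outside edges."""
    center = 0.5 * (low + high)
    halfwidth = 0.5 * (high - low)
    x = (lam - center) / halfwidth
    taper = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return taper


def make_class_signature(spec: ClassSpec, grid: BandGrid, seed: int = 0) -> np.ndarray:
    """Mean reflectance curve of one class on ``grid``.

    The healthy baseline of ``spec.crop`` is modulated multiplicatively by
    ``reflectance_delta`` inside each key window with a raised-cosine taper
    (full effect at the window center, smoothly vanishing at the edges):
    R_dis = R_healthy * (1 + delta * taper). Deterministic given ``seed``.
    """
    lam = grid.wavelengths_nm
    for low, high in spec.key_windows:
        if low < lam[0] or high > lam[-1]:
            raise ValueError(
                f"key window ({low}, {high}) outside grid range "
                f"[{lam[0]}, {lam[-1]}] nm")
    base = healthy_baseline(spec.crop, grid, seed=seed)
    if spec.is_healthy:
        return base
    modulation = np.zeros_like(lam)
    for low, high in spec.key_windows:
        modulation = np.maximum(modulation, _window_taper(lam, low, high))
    return np.clip(base * (1.0 + spec.reflectance_delta * modulation), 0.0, 1.2)


def soil_signature(grid: BandGrid) -> np.ndarray:
    """Flat, slowly rising soil spectrum with low NIR (NDVI ~ 0.04)."""
    lam = grid.wavelengths_nm
    return 0.15 + 1e-4 * (lam - 400.0)


# ---------------------------------------------------------------------------
# scene simulation
# ---------------------------------------------------------------------------

@dataclass
class _SimulatedScene:
    cube: ReflectanceCube
    lesion_mask: np.ndarray
    leaf_mask: np.ndarray


def _ellipse_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Random rotated ellipse covering roughly a third of the frame."""
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
    ay = rng.uniform(0.28, 0.40) * h
    ax = rng.uniform(0.28, 0.40) * w
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    return (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0


def _lesion_mask(leaf: np.ndarray, density: float, rng: np.random.Generator,
                 radius_frac: float = 0.05, radius_sigma: float = 0.25
                 ) -> np.ndarray:
    """Union of discs with Poisson count and log-normal radius, on the leaf."""
    h, w = leaf.shape
    mask = np.zeros_like(leaf, dtype=bool)
    n = rng.poisson(density)
    if n == 0:
        return mask
    leaf_idx = np.flatnonzero(leaf)
    if leaf_idx.size == 0:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        flat = rng.choice(leaf_idx)
        cy, cx = divmod(int(flat), w)
        radius = rng.lognormal(mean=np.log(radius_frac * min(h, w)),
                               sigma=radius_sigma)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask & leaf


def simulate_cube(spec: ClassSpec, grid: BandGrid, height: int, width: int,
                  seed: int, noise: bool = True, illumination: bool = True,
                  noise_sd: float = 0.01, noise_rho: float = 0.8,
                  illumination_sd: float = 0.05, systemic_fraction: float = 0.4,
                  lesion_radius_frac: float = 0.05, lesion_radius_sigma: float = 0.25,
                  _label: int | None = None, _split: str | None = None
                  ) -> _SimulatedScene:
    """Simulate one labelled hyperspectral scene.

    The background carries the soil spectrum, the leaf the healthy crop
    signature, and lesion blobs the diseased signature. Diseased leaves
    additionally express a systemic whole-leaf response: non-lesion leaf
    pixels carry ``systemic_fraction`` of the class reflectance deviation
    (disease physiology alters the whole leaf, with full expression only
    inside lesions). Optional AR(1) band-correlated Gaussian noise
    (correlation ``noise_rho`` across bands, per-band sd ``noise_sd``)
    and a smooth multiplicative illumination field (Gaussian-blurred
    white noise, sd ``illumination_sd``) are applied last. Bit-identical
    given identical arguments and seed.
    """
    if height < 64 or width < 64:
        raise ValueError("scene must be at least 64 x 64 pixels")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5CE17]))

    leaf = _ellipse_mask(height, width, rng)
    if spec.lesion_density > 0:
        lesion = _lesion_mask(leaf, spec.lesion_density, rng,
                              radius_frac=lesion_radius_frac,
                              radius_sigma=lesion_radius_sigma)
    else:
        lesion = np.zeros_like(leaf)

    base = healthy_baseline(spec.crop, grid, seed=seed)
    diseased = make_class_signature(spec, grid, seed=seed)
    soil = soil_signature(grid)

    data = np.empty((height, width, grid.n_bands), dtype=np.float64)
    data[:] = soil
    if spec.is_healthy or systemic_fraction == 0.0:
        data[leaf] = base
    else:
        systemic = np.clip(base + systemic_fraction * (diseased - base), 0.0, 1.2)
        data[leaf] = systemic
    data[lesion] = diseased

    if illumination:
        field = rng.standard_normal((height, width))
        field = gaussian_filter(field, sigma=min(height, width) / 8.0)
        sd = field.std()
        if sd > 0:
            field = 1.0 + illumination_sd * field / sd
        else:  # pragma: no cover - degenerate blur
            field = np.ones_like(field)
        data *= field[:, :, None]

    if noise:
        z = rng.standard_normal(data.shape)
        # AR(1) along the band axis: e_b = rho e_{b-1} + sqrt(1-rho^2) z_b
        ar = lfilter([np.sqrt(1.0 - noise_rho**2)], [1.0, -noise_rho], z, axis=2)
        data += noise_sd * ar

    np.clip(data, 0.0, 1.2, out=data)
    cube = ReflectanceCube(data=data, grid=grid)
    return _SimulatedScene(cube=cube, lesion_mask=lesion, leaf_mask=leaf)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def _sample_seed(master_seed: int, class_id: int, split_id: int, index: int) -> int:
    """Splittable per-sample seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                 class_id, split_id, index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def plan_dataset(specs: list[ClassSpec], grid: BandGrid, seed: int,
                 height: int = 256, width: int = 256,
                 **cube_kwargs) -> dict[str, list[SyntheticSample]]:
    """Lay out a dataset without generating rasters.

    Returns ``{"train": [...], "val": [...], "test": [...]}`` of lazy
    :class:`SyntheticSample` objects with per-sample seeds already fixed;
    accessing ``.cube`` on any of them materializes that scene alone.
    """
    if not specs:
        raise ValueError("at least one class spec is required")
    out: dict[str, list[SyntheticSample]] = {s: [] for s in SPLITS}
    for class_id, spec in enumerate(specs):
        for split_id, split in enumerate(SPLITS):
            for index in range(spec.counts[split_id]):
                s = _sample_seed(seed, class_id, split_id, index)
                out[split].append(SyntheticSample(
                    spec=spec, label=class_id, split=split, seed=s,
                    grid=grid, height=height, width=width, params=cube_kwargs))
    return out


def simulate_dataset(specs: list[ClassSpec], grid: BandGrid, seed: int,
                     height: int = 256, width: int = 256,
                     materialize: bool = True,
                     **cube_kwargs) -> dict[str, list[SyntheticSample]]:
    """Generate a full dataset partitioned into train/val/test.

    Exactly ``spec.counts[split]`` samples per class per split; per-sample
    seeds derive deterministically from the master seed, so the same call
    reproduces the identical dataset. With ``materialize=False`` the
    rasters stay lazy (useful for split bookkeeping on large layouts).
    """
    plan = plan_dataset(specs, grid, seed, height=height, width=width,
                        **cube_kwargs)
    if materialize:
        for split in SPLITS:
            for sample in plan[split]:
                sample._materialize()
    return plan


def table2_specs() -> list[ClassSpec]:
    """The 16 crop-disease classes of the intercropping dataset layout.

    Per-class train/val/test counts and key wavelength windows follow the
    published dataset description; the rows sum to 7,190 / 1,438 / 1,438
    = 10,066 samples (the description's own Total row prints different,
    internally inconsistent figures; the per-class rows are used).
    Reflectance deltas and lesion densities are simulator design values:
    chlorotic/pustule diseases raise visible-window reflectance (positive
    delta), necrotic/wilt diseases depress the red-edge/NIR windows
    (negative delta), and lesion densities differ across diseases.
    """
    rows = [
        ("maize", "healthy", (), 0.0, 0.0, (500, 100, 100)),
        ("maize", "leaf_spot", ((540, 580), (700, 740)), 0.18, 8.0, (450, 90, 90)),
        ("maize", "rust", ((550, 600), (720, 740)), 0.28, 12.0, (460, 92, 92)),
        ("maize", "combined_infection", ((540, 580), (680, 740)), -0.16, 9.0, (400, 80, 80)),
        ("soybean", "healthy", (), 0.0, 0.0, (480, 96, 96)),
        ("soybean", "rust", ((550, 600), (710, 730)), 0.24, 10.0, (420, 84, 84)),
        ("pea", "healthy", (), 0.0, 0.0, (500, 100, 100)),
        ("pea", "ascochyta_blight", ((530, 570), (700, 730)), 0.18, 7.0, (450, 90, 90)),
        ("pea", "powdery_mildew", ((550, 600), (710, 740)), 0.30, 13.0, (440, 88, 88)),
        ("pea", "downy_mildew", ((540, 590), (700, 730)), -0.18, 8.0, (430, 86, 86)),
        ("pea", "fusarium_wilt", ((550, 600), (710, 740)), -0.28, 5.0, (420, 84, 84)),
        ("cucumber", "healthy", (), 0.0, 0.0, (500, 100, 100)),
        ("cucumber", "angular_leaf_spot", ((540, 580), (710, 740)), 0.20, 9.0, (450, 90, 90)),
        ("cucumber", "powdery_mildew", ((550, 600), (710, 740)), 0.33, 14.0, (440, 88, 88)),
        ("cucumber", "downy_mildew", ((540, 590), (700, 730)), -0.22, 6.0, (430, 86, 86)),
        ("cucumber", "anthracnose", ((550, 600), (720, 740)), -0.30, 10.0, (420, 84, 84)),
    ]
    return [ClassSpec(crop=c, disease=d, key_windows=w, reflectance_delta=delta,
                      lesion_density=dens, counts=n)
            for c, d, w, delta, dens, n in rows]


# ---------------------------------------------------------------------------
# tabular feature benchmark
# ---------------------------------------------------------------------------

def simulate_feature_benchmark(n_samples: int, n_classes: int,
                               n_informative: int, n_redundant: int,
                               n_noise: int, effect: float,
                               seed: int) -> FeatureBenchmark:
    """Labelled feature matrix with a known relevant/irrelevant partition.

    Informative columns are Normal(mu_c, 1). Class means are laid out so
    that every informative feature is individually necessary: class 0 sits
    at the origin and class c differs from it by ``effect`` along
    informative axis (c-1) mod n_informative (classes that revisit an axis
    move further out along it). Dropping any informative column therefore
    collapses at least one class pair whenever n_classes > n_informative.
    Redundant columns are random linear combinations of the informative
    ones plus Normal(0, 0.05) noise; noise columns are Normal(0, 1)
    independent of the label. Column order is shuffled and the
    ground-truth index sets are recorded.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative feature")
    if n_samples < 10 * n_classes:
        raise ValueError("need at least 10 samples per class")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xFB]))
    y = np.repeat(np.arange(n_classes), int(np.ceil(n_samples / n_classes)))[:n_samples]
    rng.shuffle(y)

    class_means = np.zeros((n_classes, n_informative))
    for c in range(1, n_classes):
        axis = (c - 1) % n_informative
        class_means[c, axis] = effect * (1 + (c - 1) // n_informative)
    X_inf = class_means[y] + rng.standard_normal((n_samples, n_informative))
    blocks = [X_inf]
    if n_redundant > 0:
        A = rng.standard_normal((n_informative, n_redundant))
        A /= np.linalg.norm(A, axis=0, keepdims=True)
        blocks.append(X_inf @ A + 0.05 * rng.standard_normal((n_samples, n_redundant)))
    if n_noise > 0:
        blocks.append(rng.standard_normal((n_samples, n_noise)))
    X = np.concatenate(blocks, axis=1)

    n_features = n_informative + n_redundant + n_noise
    perm = rng.permutation(n_features)
    X = X[:, perm]
    inv = np.empty(n_features, dtype=int)
    inv[perm] = np.arange(n_features)
    return FeatureBenchmark(
        X=X, y=y,
        informative_idx=np.sort(inv[:n_informative]),
        redundant_idx=np.sort(inv[n_informative:n_informative + n_redundant]),
        noise_idx=np.sort(inv[n_informative + n_redundant:]),
    )
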