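"""Reflectance calibration, smoothing, masking, tiling and fold planning.

The preprocessing chain mirrors standard field-spectroscopy practice:

1. radiometric calibration against white (99%) and black (0%) reference
   panels, R = (DN - black) / (white - black), clamped to [0, 1.5];
2. Savitzky-Golay smoothing along the spectral axis (window 11, cubic);
3. spatial normalization to 256 x 256 by bilinear interpolation
   (align-corners sampling convention);
4. vegetation isolation by a hybrid NDVI (> 0.35) AND Otsu mask;
5. per-band Z-score standardization with statistics computed strictly
   from the training fold of the running cross-validation iteration;
6. tiling into non-overlapping 64 x 64 patches, all bands retained;
7. stratified 10-fold cross-validation planning.

ENVI raster I/O (text header + raw binary; BSQ/BIL/BIP read, BSQ write)
is included so cubes interchange with standard hyperspectral tooling.
Coordinate convention throughout: row-major, 0-based, half-open patch
intervals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import savgol_coeffs
from skimage.filters import threshold_otsu

from .cube import BandGrid, ReflectanceCube

__all__ = [
    "RawScene", "BandStats", "PatchSet", "FoldPlan",
    "read_envi", "write_envi", "calibrate_reflectance", "savgol_smooth",
    "resize_bilinear", "vegetation_mask", "compute_band_stats",
    "zscore_bands", "tile_patches", "reassemble_patches", "stratified_folds",
    "EnviFormatError", "EnviCorruptionError",
]

logger = logging.getLogger(__name__)

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Header missing required fields or malformed."""


class EnviCorruptionError(ValueError):
    """Binary payload inconsistent with the declared dimensions."""


@dataclass
class RawScene:
    """Uncalibrated digital numbers plus panel references."""

    dn: np.ndarray
    white_ref: np.ndarray
    black_ref: np.ndarray
    grid: BandGrid

    def __post_init__(self):
        self.dn = np.asarray(self.dn, dtype=np.float64)
        self.white_ref = np.asarray(self.white_ref, dtype=np.float64)
        self.black_ref = np.asarray(self.black_ref, dtype=np.float64)
        if self.dn.shape[2] != self.grid.n_bands:
            raise ValueError("band count mismatch")


@dataclass
class BandStats:
    """Per-band mean/sd, valid only if computed from training pixels."""

    mean: np.ndarray
    sd: np.ndarray
    source_fold: int = -1

    SD_FLOOR = 1e-8


@dataclass
class PatchSet:
    """Non-overlapping tiles of one or more cubes, row-major order."""

    patches: np.ndarray          # (n, size, size, B)
    labels: np.ndarray           # (n,)
    sample_ids: np.ndarray       # (n,) source sample index
    positions: np.ndarray        # (n, 2) top-left (row, col)
    size: int


@dataclass
class FoldPlan:
    """Stratified fold assignment: sample index -> fold id."""

    k: int
    assignment: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# ENVI raster I/O
# ---------------------------------------------------------------------------

def write_envi(cube: ReflectanceCube, path: str | Path) -> Path:
    """Write a cube as ENVI band-sequential raster + text header.

    ``path`` may omit the extension; ``<path>.hdr`` and ``<path>.raw`` are
    produced. Data are stored float64 BSQ with the wavelength list in the
    header, so a write -> read round trip is bit-exact.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    raw = path.with_suffix(".raw")
    hdr = path.with_suffix(".hdr")
    h, w, b = cube.shape
    data = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)))  # BSQ
    data.astype(np.float64).tofile(raw)
    wl = ", ".join(f"{x:.4f}" for x in cube.grid.wavelengths_nm)
    hdr.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float64)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return hdr


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # brace-delimited values may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str | Path) -> ReflectanceCube:
    """Read an ENVI raster (BSQ, BIL or BIP interleave) into a cube."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    for req in ("samples", "lines", "bands", "data type"):
        if req not in fields:
            raise EnviFormatError(f"header missing required field '{req}'")
    w = int(fields["samples"])
    h = int(fields["lines"])
    b = int(fields["bands"])
    dtype = _ENVI_DTYPES.get(int(fields["data type"]))
    if dtype is None:
        raise EnviFormatError(f"unsupported data type {fields['data type']}")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))

    raw_path = header_path.with_suffix(".raw")
    if not raw_path.exists():
        for ext in (".img", ".dat", ""):
            cand = header_path.with_suffix(ext)
            if cand.exists() and cand != header_path:
                raw_path = cand
                break
    payload = np.fromfile(raw_path, dtype=dtype, offset=offset)
    if payload.size != h * w * b:
        raise EnviCorruptionError(
            f"binary holds {payload.size} values, header declares {h * w * b}")
    if interleave == "bsq":
        data = payload.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        data = payload.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        data = payload.reshape(h, w, b)
    else:
        raise EnviFormatError(f"unknown interleave '{interleave}'")

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip("{} ")
        wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()])
        if wavelengths.size != b:
            raise EnviCorruptionError("wavelength list length != band count")
    else:
        wavelengths = np.linspace(400.0, 1000.0, b)
    return ReflectanceCube(data=np.ascontiguousarray(data, dtype=np.float64),
                           grid=BandGrid(wavelengths))


# ---------------------------------------------------------------------------
# calibration and smoothing
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: RawScene, clamp: tuple[float, float] = (0.0, 1.5)
                          ) -> ReflectanceCube:
    """Panel calibration R = (DN - black) / (white - black), clamped.

    The clamp ceiling of 1.5 tolerates specular highlights that exceed the
    white panel without letting them dominate later statistics.
    """
    span = raw.white_ref - raw.black_ref
    if np.any(span <= 0):
        raise ValueError("white reference must exceed black reference in every band")
    refl = (raw.dn - raw.black_ref) / span
    return ReflectanceCube(data=np.clip(refl, *clamp), grid=raw.grid)


def savgol_smooth(cube: ReflectanceCube, window: int = 11, polyorder: int = 3
                  ) -> ReflectanceCube:
    """Savitzky-Golay smoothing along the spectral axis.

    Interior bands are convolved with the least-squares kernel. At the
    spectrum ends, the polynomial is re-fitted on the truncated one-sided
    window actually available (no reflection padding), which preserves the
    degree-<=polyorder reproduction property everywhere.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    b = cube.grid.n_bands
    if b < window:
        raise ValueError(f"need at least {window} bands, have {b}")
    half = window // 2
    x = cube.data
    flat = x.reshape(-1, b)
    out = np.empty_like(flat)

    kernel = savgol_coeffs(window, polyorder, deriv=0)  # symmetric for deriv=0
    windows = np.lib.stride_tricks.sliding_window_view(flat, window, axis=1)
    out[:, half:b - half] = windows @ kernel

    # truncated-window ends: refit the polynomial on the available bands
    for i in list(range(half)) + list(range(b - half, b)):
        lo, hi = max(0, i - half), min(b, i + half + 1)
        t = np.arange(lo, hi) - i
        V = np.vander(t, polyorder + 1, increasing=True)
        # row of the hat matrix evaluated at t = 0
        coeffs = np.linalg.lstsq(V, np.eye(hi - lo), rcond=None)[0][0]
        out[:, i] = flat[:, lo:hi] @ coeffs
    return cube.with_data(out.reshape(x.shape))


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def resize_bilinear(cube: ReflectanceCube, out_h: int = 256, out_w: int = 256
                    ) -> ReflectanceCube:
    """Band-wise bilinear resize with align-corners sampling.

    Output pixel (i, j) samples the source at
    (i * (H-1)/(out_h-1), j * (W-1)/(out_w-1)); corner pixels map to
    corner pixels exactly, and matching sizes are the identity.
    """
    h, w, _ = cube.shape
    if h < 2 or w < 2:
        raise ValueError("source must be at least 2 x 2")
    if (out_h, out_w) == (h, w):
        return cube.with_data(cube.data.copy())
    ys = np.linspace(0.0, h - 1.0, out_h)
    xs = np.linspace(0.0, w - 1.0, out_w)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 2)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 2)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    d = cube.data
    top = d[y0][:, x0] * (1 - fx) + d[y0][:, x0 + 1] * fx
    bot = d[y0 + 1][:, x0] * (1 - fx) + d[y0 + 1][:, x0 + 1] * fx
    return cube.with_data(top * (1 - fy) + bot * fy)


def vegetation_mask(cube: ReflectanceCube, ndvi_threshold: float = 0.35,
                    red_nm: float = 670.0, nir_nm: float = 800.0,
                    eps: float = 1e-8) -> np.ndarray:
    """Hybrid vegetation mask: NDVI > threshold AND NIR above Otsu.

    NDVI = (NIR - red) / (NIR + red + eps) with the bands nearest 670 nm
    (red) and 800 nm (NIR). The Otsu threshold is computed on the NIR
    band, suppressing bright non-vegetation surfaces that pass the NDVI
    test; the two criteria are fused by logical AND.
    """
    w = cube.grid.wavelengths_nm
    if not ((w >= 660) & (w <= 690)).any():
        raise ValueError("grid lacks a red band in 660-690 nm")
    if not ((w >= 780) & (w <= 870)).any():
        raise ValueError("grid lacks an NIR band in 780-870 nm")
    red = cube.data[:, :, cube.grid.index_of(red_nm)]
    nir = cube.data[:, :, cube.grid.index_of(nir_nm)]
    ndvi = (nir - red) / (nir + red + eps)
    ndvi_ok = ndvi > ndvi_threshold
    if nir.max() - nir.min() < 1e-12:
        otsu_ok = np.ones_like(ndvi_ok)
    else:
        otsu_ok = nir > threshold_otsu(nir)
    return ndvi_ok & otsu_ok


# ---------------------------------------------------------------------------
# standardization (leakage-guarded)
# ---------------------------------------------------------------------------

def compute_band_stats(cubes: list[ReflectanceCube] | np.ndarray,
                       source_fold: int = -1) -> BandStats:
    """Per-band mean/sd over the pixels of training-fold cubes only.

    Callers are responsible for passing *training* data; the fold id is
    recorded so downstream artifacts can assert provenance.
    """
    if isinstance(cubes, np.ndarray):
        flat = cubes.reshape(-1, cubes.shape[-1])
    else:
        flat = np.concatenate([c.data.reshape(-1, c.shape[-1]) for c in cubes])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    floored = sd < BandStats.SD_FLOOR
    if floored.any():
        logger.warning("sd floor triggered in %d band(s)", int(floored.sum()))
        sd = np.where(floored, BandStats.SD_FLOOR, sd)
    return BandStats(mean=mean, sd=sd, source_fold=source_fold)


def zscore_bands(cube: ReflectanceCube, stats: BandStats) -> ReflectanceCube:
    """Per-band standardization (x - mean_b) / sd_b with training stats."""
    return cube.with_data((cube.data - stats.mean) / stats.sd)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_patches(cube: ReflectanceCube, size: int = 64,
                 label: int = -1, sample_id: int = 0) -> PatchSet:
    """Cut a cube into non-overlapping size x size patches, all bands kept.

    Requires H and W divisible by ``size`` (guaranteed after the 256 x 256
    resize for the default size 64); patches come out in row-major order.
    """
    h, w, b = cube.shape
    if h % size or w % size:
        raise ValueError(f"{h} x {w} not divisible by patch size {size}")
    ny, nx = h // size, w // size
    patches = (cube.data
               .reshape(ny, size, nx, size, b)
               .transpose(0, 2, 1, 3, 4)
               .reshape(ny * nx, size, size, b))
    positions = np.array([(i * size, j * size) for i in range(ny) for j in range(nx)])
    n = ny * nx
    return PatchSet(patches=patches, labels=np.full(n, label),
                    sample_ids=np.full(n, sample_id), positions=positions,
                    size=size)


def reassemble_patches(ps: PatchSet, height: int, width: int,
                       grid: BandGrid) -> ReflectanceCube:
    """Inverse of :func:`tile_patches` for a single source cube."""
    b = ps.patches.shape[-1]
    data = np.zeros((height, width, b))
    for patch, (r, c) in zip(ps.patches, ps.positions):
        data[r:r + ps.size, c:c + ps.size] = patch
    return ReflectanceCube(data=data, grid=grid)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan: per-class fold sizes differ by at most one.

    Samples of each class are shuffled with the seeded generator and dealt
    round-robin across folds, so class balance is preserved in every fold
    and the plan is deterministic given the seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xF01D]))
    assignment = np.full(labels.size, -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)
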