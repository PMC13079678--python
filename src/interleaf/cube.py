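"""Core raster types shared across the pipeline.

A hyperspectral scene is represented as an H x W x B reflectance array
(two spatial axes, one spectral axis) together with the grid of band-center
wavelengths. Reflectance is dimensionless (0 = black panel, 1 = white
panel); values slightly above 1 can occur on specular highlights and are
clamped downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BandGrid", "ReflectanceCube", "default_grid"]


@dataclass(frozen=True)
class BandGrid:
    """Ordered band-center wavelengths of a hyperspectral sensor, in nm.

    Wavelengths must be strictly increasing and lie in the 400-1000 nm
    VNIR range; at least 8 bands are required for the spectral operators
    (Savitzky-Golay smoothing, NDVI, red-edge localization) to be defined.
    """

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        if w.ndim != 1 or w.size < 8:
            raise ValueError("band grid needs at least 8 wavelengths")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if w[0] < 400.0 - 1e-9 or w[-1] > 1000.0 + 1e-9:
            raise ValueError("wavelengths must lie within [400, 1000] nm")

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.size)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))

    def band_slice(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Boolean selector of bands whose centers fall in [low, high] nm."""
        w = self.wavelengths_nm
        sel = (w >= low_nm) & (w <= high_nm)
        if not sel.any():
            raise ValueError(f"no bands in window [{low_nm}, {high_nm}] nm")
        return sel


def default_grid() -> BandGrid:
    """61 bands, 400-1000 nm at 10 nm spacing (the package default)."""
    return BandGrid(np.arange(400.0, 1000.0 + 1e-9, 10.0))


@dataclass
class ReflectanceCube:
    """H x W x B reflectance raster with its band grid and optional mask.

    ``mask`` (when present) is a boolean H x W vegetation map; it is carried
    through band-wise operators unchanged.
    """

    data: np.ndarray
    grid: BandGrid
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ReflectanceCube":
        """Same grid/mask, new array (used by band-wise operators)."""
        return ReflectanceCube(data=data, grid=self.grid, mask=self.mask)
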