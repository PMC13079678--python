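"""The preprocessing chain: calibration, smoothing, resize, mask, folds.

Starts from raw digital numbers with white/black panel references,
calibrates to reflectance, smooths along the spectral axis with the
Savitzky-Golay filter (window 11, cubic), resizes band-wise with
align-corners bilinear interpolation, isolates vegetation with the
hybrid NDVI + Otsu mask, and plans a stratified 10-fold split.
"""

import numpy as np

from interleaf import preprocess as pp
from interleaf import simkit
from interleaf.cube import default_grid

grid = default_grid()
scene = simkit.simulate_cube(simkit.table2_specs()[1], grid, 64, 64, seed=2)

# pretend the scene was recorded as digital numbers with panel references
white = np.full(grid.n_bands, 4000.0)
black = np.full(grid.n_bands, 120.0)
dn = black + scene.cube.data * (white - black)
raw = pp.RawScene(dn=dn, white_ref=white, black_ref=black, grid=grid)

cube = pp.calibrate_reflectance(raw)
print(f"calibration round-trip error: "
      f"{np.abs(cube.data - scene.cube.data).max():.2e}")

smooth = pp.savgol_smooth(cube, window=11, polyorder=3)
print(f"Savitzky-Golay mean |change|: "
      f"{np.abs(smooth.data - cube.data).mean():.5f} (noise removed)")

big = pp.resize_bilinear(smooth, 256, 256)
mask = pp.vegetation_mask(big)
print(f"resized to {big.shape[:2]}, vegetation mask covers "
      f"{100 * mask.mean():.1f}% of the frame")

patches = pp.tile_patches(big, size=64)
print(f"tiled into {len(patches.patches)} non-overlapping 64x64 patches")

labels = np.array([0] * 700 + [1] * 630)      # published class sizes
plan = pp.stratified_folds(labels, k=10, seed=0)
sizes = [( (labels[plan.assignment == f] == 0).sum(),
           (labels[plan.assignment == f] == 1).sum()) for f in range(10)]
print(f"stratified 10-fold sizes per class (first 3 folds): {sizes[:3]}")
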