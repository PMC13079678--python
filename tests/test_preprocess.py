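"""Calibration, smoothing, masking, tiling, folds and ENVI round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from interleaf import preprocess as pp
from interleaf.cube import BandGrid, ReflectanceCube


def small_grid(n=8, lo=400.0, hi=1000.0):
    return BandGrid(np.linspace(lo, hi, n))


def random_cube(rng, h=6, w=5, b=12):
    return ReflectanceCube(rng.random((h, w, b)), small_grid(b))


class TestEnviIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        cube = random_cube(rng, 8, 8, 9)
        hdr = pp.write_envi(cube, tmp_path / "scene")
        back = pp.read_envi(hdr)
        assert np.array_equal(back.data, cube.data)
        assert np.array_equal(back.grid.wavelengths_nm, cube.grid.wavelengths_nm)

    def test_corruption_detected(self, tmp_path):
        """Header declares 5 bands but the binary only holds 4."""
        rng = np.random.default_rng(0)
        hdr = pp.write_envi(random_cube(rng, 4, 4, 9), tmp_path / "scene")
        raw = tmp_path / "scene.raw"
        payload = raw.read_bytes()
        raw.write_bytes(payload[: 4 * 4 * 8 * 8])
        with pytest.raises(pp.EnviCorruptionError):
            pp.read_envi(hdr)

    def test_missing_field_raises(self, tmp_path):
        (tmp_path / "bad.hdr").write_text("ENVI\nsamples = 4\nlines = 4\n")
        with pytest.raises(pp.EnviFormatError, match="bands"):
            pp.read_envi(tmp_path / "bad.hdr")

    def test_bil_matches_bsq(self, tmp_path):
        """The same tiny array stored BIL reads back identically to BSQ."""
        rng = np.random.default_rng(1)
        data = rng.random((3, 4, 8))
        cube = ReflectanceCube(data, small_grid(8))
        hdr = pp.write_envi(cube, tmp_path / "bsq")
        # hand-build the BIL layout: rows x bands x columns
        bil = np.transpose(data, (0, 2, 1)).astype(np.float64)
        (tmp_path / "bil.raw").write_bytes(bil.tobytes())
        (tmp_path / "bil.hdr").write_text(
            hdr.read_text().replace("interleave = bsq", "interleave = bil"))
        assert np.array_equal(pp.read_envi(tmp_path / "bil.hdr").data, data)


class TestCalibration:
    def setup_method(self):
        self.grid = small_grid(10)
        rng = np.random.default_rng(2)
        self.white = 4000 + 500 * rng.random(10)
        self.black = 100 + 50 * rng.random(10)

    def raw(self, dn):
        return pp.RawScene(dn=dn, white_ref=self.white, black_ref=self.black,
                           grid=self.grid)

    def test_black_gives_zero(self):
        dn = np.broadcast_to(self.black, (4, 4, 10)).copy()
        assert np.allclose(pp.calibrate_reflectance(self.raw(dn)).data, 0.0)

    def test_white_gives_one(self):
        dn = np.broadcast_to(self.white, (4, 4, 10)).copy()
        assert np.allclose(pp.calibrate_reflectance(self.raw(dn)).data, 1.0)

    def test_quarter_point(self):
        dn = np.broadcast_to(self.black + 0.25 * (self.white - self.black),
                             (4, 4, 10)).copy()
        assert np.allclose(pp.calibrate_reflectance(self.raw(dn)).data, 0.25)

    def test_equal_panels_raise(self):
        raw = pp.RawScene(dn=np.zeros((2, 2, 10)), white_ref=self.black,
                          black_ref=self.black, grid=self.grid)
        with pytest.raises(ValueError, match="white reference"):
            pp.calibrate_reflectance(raw)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(0.5, 3.0), offset=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(3)
        dn = self.black + (self.white - self.black) * rng.random((3, 3, 10))
        plain = pp.calibrate_reflectance(self.raw(dn))
        scaled = pp.RawScene(dn=scale * dn + offset,
                             white_ref=scale * self.white + offset,
                             black_ref=scale * self.black + offset,
                             grid=self.grid)
        assert np.allclose(pp.calibrate_reflectance(scaled).data, plain.data,
                           atol=1e-9)


class TestSavgol:
    def test_cubic_is_fixed_point_everywhere(self):
        grid = small_grid(61)
        idx = np.arange(61, dtype=float)
        spectrum = 1e-3 * (0.4 + 0.2 * idx - 0.01 * idx**2 + 3e-4 * idx**3)
        cube = ReflectanceCube(np.tile(spectrum, (3, 3, 1)), grid)
        out = pp.savgol_smooth(cube)
        assert np.abs(out.data - cube.data).max() < 1e-9  # incl. the edges

    def test_constant_unchanged(self):
        cube = ReflectanceCube(np.full((2, 2, 15), 0.3), small_grid(15))
        assert np.allclose(pp.savgol_smooth(cube).data, 0.3)

    def test_interior_matches_local_least_squares_oracle(self):
        """Brute-force oracle: fit a cubic to each 11-band window."""
        rng = np.random.default_rng(4)
        b = 31
        spectrum = rng.random(b)
        cube = ReflectanceCube(spectrum.reshape(1, 1, b), small_grid(b))
        out = pp.savgol_smooth(cube).data[0, 0]
        for i in range(5, b - 5):
            t = np.arange(-5, 6, dtype=float)
            V = np.vander(t, 4, increasing=True)
            coeffs, *_ = np.linalg.lstsq(V, spectrum[i - 5:i + 6], rcond=None)
            assert out[i] == pytest.approx(coeffs[0], abs=1e-10)

    def test_bad_window_raises(self):
        cube = ReflectanceCube(np.zeros((2, 2, 15)), small_grid(15))
        with pytest.raises(ValueError):
            pp.savgol_smooth(cube, window=10)
        with pytest.raises(ValueError):
            pp.savgol_smooth(cube, window=3, polyorder=3)


class TestResize:
    def test_identity_when_sizes_match(self):
        rng = np.random.default_rng(5)
        cube = random_cube(rng, 7, 7, 8)
        assert np.array_equal(pp.resize_bilinear(cube, 7, 7).data, cube.data)

    def test_hand_bilinear_2x2_to_3x3(self):
        data = np.array([[0.0, 1.0], [2.0, 3.0]]).reshape(2, 2, 1)
        cube = ReflectanceCube(np.repeat(data, 8, axis=2), small_grid(8))
        out = pp.resize_bilinear(cube, 3, 3).data[:, :, 0]
        expected = np.array([[0.0, 0.5, 1.0], [1.0, 1.5, 2.0], [2.0, 2.5, 3.0]])
        assert np.allclose(out, expected)

    def test_constant_stays_constant(self):
        cube = ReflectanceCube(np.full((5, 4, 8), 0.7), small_grid(8))
        assert np.allclose(pp.resize_bilinear(cube, 11, 13).data, 0.7)

    def test_corners_are_preserved(self):
        rng = np.random.default_rng(6)
        cube = random_cube(rng, 6, 6, 8)
        out = pp.resize_bilinear(cube, 17, 9)
        for (i, j), (oi, oj) in zip([(0, 0), (0, 5), (5, 0), (5, 5)],
                                    [(0, 0), (0, 8), (16, 0), (16, 8)]):
            assert np.allclose(out.data[oi, oj], cube.data[i, j])


class TestVegetationMask:
    def test_ndvi_formula_pixel(self, grid):
        data = np.full((4, 4, grid.n_bands), 0.05)
        data[:2, :, grid.index_of(800)] = 0.50     # vegetation-like pixels
        cube = ReflectanceCube(data, grid)
        mask = pp.vegetation_mask(cube)
        assert mask[:2].all() and not mask[2:].any()

    def test_equal_red_nir_fails_ndvi(self, grid):
        cube = ReflectanceCube(np.full((3, 3, grid.n_bands), 0.4), grid)
        assert not pp.vegetation_mask(cube).any()

    def test_simulated_scene_dice(self, grid, leafspot_scene):
        mask = pp.vegetation_mask(leafspot_scene.cube)
        truth = leafspot_scene.leaf_mask
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice > 0.95

    def test_missing_bands_raise(self):
        cube = ReflectanceCube(np.zeros((2, 2, 8)), small_grid(8, 400, 600))
        with pytest.raises(ValueError, match="band"):
            pp.vegetation_mask(cube)


class TestZScore:
    def test_self_stats_normalize(self):
        rng = np.random.default_rng(7)
        cube = random_cube(rng, 10, 10, 9)
        stats = pp.compute_band_stats([cube])
        z = pp.zscore_bands(cube, stats).data.reshape(-1, 9)
        assert np.abs(z.mean(axis=0)).max() < 1e-6
        assert np.abs(z.std(axis=0) - 1).max() < 1e-6

    def test_constant_band_floored_to_zero(self):
        data = np.random.default_rng(8).random((4, 4, 8))
        data[:, :, 2] = 0.5
        cube = ReflectanceCube(data, small_grid(8))
        stats = pp.compute_band_stats([cube])
        assert stats.sd[2] == pp.BandStats.SD_FLOOR
        assert np.allclose(pp.zscore_bands(cube, stats).data[:, :, 2], 0.0)

    def test_unit_displacement(self):
        rng = np.random.default_rng(9)
        cube = random_cube(rng, 6, 6, 8)
        stats = pp.compute_band_stats([cube])
        probe = ReflectanceCube(
            np.broadcast_to(stats.mean + stats.sd, (1, 1, 8)).copy(),
            cube.grid)
        assert np.allclose(pp.zscore_bands(probe, stats).data, 1.0)

    def test_leakage_guard_fold_stats_differ(self):
        """Training-fold statistics must differ from full-data statistics."""
        rng = np.random.default_rng(10)
        cubes = [random_cube(rng, 6, 6, 8) for _ in range(6)]
        full = pp.compute_band_stats(cubes)
        fold0_train = pp.compute_band_stats(cubes[2:], source_fold=0)
        assert fold0_train.source_fold == 0
        assert not np.allclose(full.mean, fold0_train.mean)


class TestTiling:
    def test_256_gives_16_patches(self):
        cube = ReflectanceCube(np.random.default_rng(11).random((256, 256, 8)),
                               small_grid(8))
        ps = pp.tile_patches(cube, size=64)
        assert ps.patches.shape == (16, 64, 64, 8)

    def test_single_patch_identity(self):
        rng = np.random.default_rng(12)
        cube = ReflectanceCube(rng.random((64, 64, 8)), small_grid(8))
        ps = pp.tile_patches(cube, size=64)
        assert np.array_equal(ps.patches[0], cube.data)

    def test_tile_reassemble_bijection(self):
        rng = np.random.default_rng(13)
        cube = ReflectanceCube(rng.random((128, 192, 8)), small_grid(8))
        ps = pp.tile_patches(cube, size=64)
        back = pp.reassemble_patches(ps, 128, 192, cube.grid)
        assert np.array_equal(back.data, cube.data)

    def test_indivisible_raises(self):
        cube = ReflectanceCube(np.zeros((100, 64, 8)), small_grid(8))
        with pytest.raises(ValueError):
            pp.tile_patches(cube, size=64)


class TestStratifiedFolds:
    def test_exact_division_table_sizes(self):
        labels = np.array([0] * 700 + [1] * 630)
        plan = pp.stratified_folds(labels, k=10, seed=0)
        for f in range(10):
            fold = plan.assignment == f
            assert (labels[fold] == 0).sum() == 70
            assert (labels[fold] == 1).sum() == 63

    def test_pigeonhole_eleven_samples(self):
        plan = pp.stratified_folds(np.zeros(11, dtype=int), k=10, seed=1)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert sorted(sizes) == [1] * 9 + [2]

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="fewer than"):
            pp.stratified_folds(np.array([0] * 20 + [1] * 5), k=10, seed=0)

    def test_deterministic_given_seed(self):
        labels = np.random.default_rng(14).integers(0, 3, 90)
        a = pp.stratified_folds(labels, k=3, seed=5)
        b = pp.stratified_folds(labels, k=3, seed=5)
        assert np.array_equal(a.assignment, b.assignment)
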