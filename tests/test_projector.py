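import numpy as np
import pytest

from tomofield.geometry import PatchPattern, Pose, Ray, RayBundle, SourceSetup, rays_for_detector, rays_for_patch
from tomofield.phantom import default_setup
from tomofield.projector import (
    VoxelGrid,
    line_integral,
    line_integrals,
    make_drr,
    render_patch_from_field,
    siddon_trace,
)


def random_bundle(grid, n, rng):
    lo, hi = grid.bounds
    origins = np.empty((n, 3))
    origins[:, 0] = lo[0] - 25.0
    origins[:, 1] = rng.uniform(lo[1] - 10, hi[1] + 10, n)
    origins[:, 2] = rng.uniform(lo[2] - 10, hi[2] + 10, n)
    targets = rng.uniform(lo, hi, (n, 3))
    dirs = targets - origins
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return RayBundle(origins, dirs, (n,))


def analytic_chord(grid, origin, direction):
    lo, hi = grid.bounds
    with np.errstate(divide="ignore"):
        t0 = (lo - origin) / direction
        t1 = (hi - origin) / direction
    tmin = max(np.minimum(t0, t1).max(), 0.0)
    tmax = np.maximum(t0, t1).min()
    return max(tmax - tmin, 0.0)


class TestVoxelGrid:
    def test_invariants(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.ones((2, 2)), 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            VoxelGrid(-np.ones((2, 2, 2)), 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            VoxelGrid(np.ones((2, 2, 2)), 0.0, np.zeros(3))

    def test_centered_bounds(self):
        g = VoxelGrid.centered(np.ones((4, 4, 4)), 2.0)
        lo, hi = g.bounds
        assert np.allclose(lo, -4.0) and np.allclose(hi, 4.0)


class TestSiddon:
    def test_single_voxel_axis_aligned(self):
        g = VoxelGrid.centered(np.ones((1, 1, 1)), 1.0)
        segs = siddon_trace(g, Ray(np.array([-5.0, 0, 0]), np.array([1.0, 0, 0])))
        assert len(segs) == 1
        assert segs[0].voxel_index == (0, 0, 0)
        assert segs[0].length_mm == pytest.approx(1.0, abs=1e-12)

    def test_miss_is_empty(self):
        g = VoxelGrid.centered(np.ones((2, 2, 2)), 1.0)
        assert siddon_trace(g, Ray(np.array([-5.0, 10.0, 0]), np.array([1.0, 0, 0]))) == []

    def test_non_unit_direction_rejected(self):
        g = VoxelGrid.centered(np.ones((2, 2, 2)), 1.0)
        with pytest.raises(ValueError):
            siddon_trace(g, Ray(np.zeros(3), np.array([2.0, 0, 0])))

    def test_conservation_and_uniqueness(self, rng):
        """Sum of segment lengths equals the analytic box chord; every voxel
        appears once; segments are ordered along the ray."""
        g = VoxelGrid.centered(rng.uniform(size=(8, 8, 8)), 1.3)
        for _ in range(250):
            b = random_bundle(g, 1, rng)
            ray = b[0]
            segs = siddon_trace(g, ray)
            total = sum(s.length_mm for s in segs)
            assert abs(total - analytic_chord(g, ray.origin_mm, ray.direction)) < 1e-6
            keys = [s.voxel_index for s in segs]
            assert len(keys) == len(set(keys))
            # ordered: consecutive voxel indices differ by a single step
            for a, b_ in zip(keys, keys[1:]):
                assert sum(abs(i - j) for i, j in zip(a, b_)) >= 1


class TestLineIntegral:
    def test_uniform_slab_thickness(self):
        g = VoxelGrid.centered(np.ones((10, 4, 4)), 1.0)
        val = line_integral(g, Ray(np.array([-50.0, 0.1, 0.1]), np.array([1.0, 0, 0])))
        assert val == pytest.approx(10.0, abs=1e-12)

    def test_cube_main_diagonal(self):
        a = 8.0
        g = VoxelGrid.centered(np.ones((8, 8, 8)), 1.0)
        d = np.ones(3) / np.sqrt(3)
        val = line_integral(g, Ray(np.array([-20.0, -20.0, -20.0]), d))
        assert val == pytest.approx(a * np.sqrt(3), abs=1e-6)

    def test_linearity(self, rng):
        vals = rng.uniform(size=(6, 6, 6))
        g1 = VoxelGrid.centered(vals, 1.0)
        g2 = VoxelGrid.centered(2 * vals, 1.0)
        ray = random_bundle(g1, 1, rng)[0]
        assert line_integral(g2, ray) == pytest.approx(2 * line_integral(g1, ray), rel=1e-9)

    def test_superposition(self, rng):
        a = rng.uniform(size=(5, 5, 5))
        b = rng.uniform(size=(5, 5, 5))
        ga, gb, gab = (VoxelGrid.centered(v, 1.0) for v in (a, b, a + b))
        ray = random_bundle(ga, 1, rng)[0]
        assert line_integral(gab, ray) == pytest.approx(
            line_integral(ga, ray) + line_integral(gb, ray), rel=1e-9)

    def test_against_fine_step_integration(self, rng):
        """Siddon equals dense numerical integration (step = spacing/1000)."""
        vals = rng.uniform(size=(8, 8, 8))
        g = VoxelGrid.centered(vals, 1.0)
        lo, _ = g.bounds
        bundle = random_bundle(g, 100, rng)
        exact = line_integrals(g, bundle)
        bundle.clip_to_box(*g.bounds)
        step = g.spacing_mm.min() / 1000
        for i in range(100):
            if not bundle.valid[i]:
                assert exact[i] == 0.0
                continue
            span = bundle.t_far[i] - bundle.t_near[i]
            n = int(np.ceil(span / step))
            ts = bundle.t_near[i] + (np.arange(n) + 0.5) * span / n
            pts = bundle.origins[i] + ts[:, None] * bundle.directions[i]
            idx = np.clip(((pts - lo) / g.spacing_mm).astype(int), 0, 7)
            approx = vals[idx[:, 0], idx[:, 1], idx[:, 2]].sum() * span / n
            assert abs(approx - exact[i]) <= 1e-3 * max(exact[i], 1e-9)


class TestDrr:
    def test_zero_grid_projects_to_zero(self, small_setup):
        g = VoxelGrid.centered(np.zeros((8, 8, 8)), 300 / 8)
        img = make_drr(g, small_setup, Pose())
        assert np.all(img == 0.0)

    def test_constant_image_normalizes_to_zero(self):
        # a huge uniform cube fully covering the detector footprint produces
        # nearly-equal integrals only in degenerate tiny-detector setups; use
        # the documented convention directly via a 1-pixel detector
        setup = SourceSetup(det_rows=1, det_cols=1, det_pitch_mm=1.0)
        g = VoxelGrid.centered(np.ones((4, 4, 4)), 10.0)
        img = make_drr(g, setup, Pose())
        assert img.shape == (1, 1) and img[0, 0] == 0.0

    def test_bright_voxel_magnification(self):
        """An off-center voxel's projected footprint obeys the sid/sad relation."""
        setup = default_setup(33, 300.0)
        vals = np.zeros((33, 33, 33))
        vals[16 + 4, 16, 16] = 1.0  # offset along +x at the isocenter plane
        g = VoxelGrid.centered(vals, 300 / 33)
        raw = make_drr(g, setup, Pose(), normalize=False)
        r, c = np.unravel_index(np.argmax(raw), raw.shape)
        offset_mm = 4 * g.spacing_mm[0]
        expected_px = offset_mm * setup.magnification / setup.det_pitch_mm
        # theta=0 detector u-axis is -x, so the footprint moves to lower columns
        assert abs((16 - c) - expected_px) <= 1.0
        assert r == 16


class TestFieldRendering:
    def test_constant_field(self, rng, small_setup):
        g = VoxelGrid.centered(np.ones((8, 8, 8)), 300 / 8)
        rays = rays_for_detector(small_setup, Pose(), bounds=g.bounds)
        img, sub = render_patch_from_field(lambda p: np.full(len(p), 0.3), rays, 16, rng)
        span = (rays.t_far - rays.t_near).reshape(rays.shape)
        assert np.allclose(img, 0.3 * span, rtol=1e-9)
        assert sub.densities.shape == (16 * 16, 16)

    def test_zero_field(self, rng, small_setup):
        g = VoxelGrid.centered(np.ones((8, 8, 8)), 300 / 8)
        rays = rays_for_detector(small_setup, Pose(), bounds=g.bounds)
        img, sub = render_patch_from_field(lambda p: np.zeros(len(p)), rays, 8, rng)
        assert np.all(img == 0.0) and np.all(sub.densities == 0.0)

    def test_converges_to_siddon(self, rng):
        """Voxel-lookup rendering approaches the exact Siddon integral as the
        per-ray sample count grows."""
        from scipy.ndimage import gaussian_filter

        vals = 0.5 + 0.5 * gaussian_filter(rng.uniform(size=(16, 16, 16)), 2.0)
        g = VoxelGrid.centered(vals, 300 / 16)
        lo, _ = g.bounds

        def lookup(pts):
            idx = np.clip(((pts - lo) / g.spacing_mm).astype(int), 0, 15)
            return vals[idx[:, 0], idx[:, 1], idx[:, 2]]

        setup = default_setup(8, 300.0)
        rays = rays_for_detector(setup, Pose(25.0), bounds=g.bounds)
        exact = line_integrals(g, rays).reshape(rays.shape)
        errs = []
        for q in (16, 64, 256):
            img, _ = render_patch_from_field(lookup, rays, q, np.random.default_rng(5))
            errs.append(np.abs(img - exact).max() / exact.max())
        assert errs[2] < errs[0]
        assert errs[2] < 0.01

    def test_unbiased_estimator(self, rng):
        """Stratified rendering is unbiased: the seed-mean of a pixel matches
        the exact integral within 3 standard errors."""
        g = VoxelGrid.centered(np.ones((4, 4, 4)), 50.0)  # bounds +-100 mm

        def smooth(pts):
            return 1.0 + 0.5 * np.sin(pts[:, 0] / 30.0) * np.cos(pts[:, 1] / 40.0)

        setup = default_setup(3, 200.0)
        rays = rays_for_detector(setup, Pose(), bounds=g.bounds)
        # exact via very fine midpoint rule
        i = 4  # central pixel
        tn, tf = rays.t_near[i], rays.t_far[i]
        ts = tn + (np.arange(200_000) + 0.5) * (tf - tn) / 200_000
        pts = rays.origins[i] + ts[:, None] * rays.directions[i]
        exact = smooth(pts).sum() * (tf - tn) / 200_000

        vals = []
        for seed in range(100):
            img, _ = render_patch_from_field(smooth, rays, 8, np.random.default_rng(seed))
            vals.append(img.reshape(-1)[i])
        vals = np.array(vals)
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - exact) < 3 * max(sem, 1e-12)
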