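import numpy as np
import pytest
from scipy import stats

from tomofield.geometry import (
    PatchPattern,
    Pose,
    SourceSetup,
    make_circular_poses,
    rays_for_detector,
    rays_for_patch,
    sample_patch_pattern,
    stratified_sample,
)


class TestSourceSetup:
    @pytest.mark.parametrize("kwargs", [
        {"sad_mm": -1.0},
        {"sid_mm": 500.0},          # must exceed sad
        {"det_rows": 0},
        {"det_pitch_mm": 0.0},
    ])
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SourceSetup(**kwargs)

    def test_magnification(self):
        assert SourceSetup(sad_mm=570, sid_mm=1040).magnification == pytest.approx(1040 / 570)


class TestCircularPoses:
    @pytest.mark.parametrize("n,expected_step", [(5, 72.0), (72, 5.0), (4, 90.0)])
    def test_equal_spacing(self, n, expected_step):
        poses = make_circular_poses(n)
        az = np.array([p.theta_deg for p in poses])
        assert np.allclose(np.diff(az), expected_step)
        assert az[0] == 0.0

    def test_five_views_every_72(self):
        az = [p.theta_deg for p in make_circular_poses(5)]
        assert az == [0.0, 72.0, 144.0, 216.0, 288.0]

    def test_single_ap_pose(self):
        poses = make_circular_poses(1)
        assert len(poses) == 1 and poses[0] == Pose(0.0, 0.0)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            make_circular_poses(0)

    def test_sources_on_ring(self):
        sad = 570.0
        for p in make_circular_poses(7, start_deg=13.0):
            assert abs(np.linalg.norm(p.source_position(sad)) - sad) < 1e-9 * sad


class TestPatchPattern:
    def test_scale_bounds_128(self, rng):
        setup = SourceSetup(det_rows=128, det_cols=128)
        scales = [sample_patch_pattern(rng, setup, 32).scale_s for _ in range(200)]
        assert min(scales) >= 1.0 and max(scales) <= 4.0

    def test_full_detector_degenerate(self, rng):
        setup = SourceSetup(det_rows=32, det_cols=32)
        pat = sample_patch_pattern(rng, setup, 32)
        assert pat.scale_s == 1.0
        assert pat.center_uv == (15.5, 15.5)

    def test_patch_too_large(self, rng):
        with pytest.raises(ValueError):
            sample_patch_pattern(rng, SourceSetup(det_rows=16, det_cols=16), 17)

    def test_footprint_inside_detector(self, rng):
        setup = SourceSetup(det_rows=64, det_cols=48)
        for _ in range(300):
            pat = sample_patch_pattern(rng, setup, 8)
            pat.validate(setup)  # raises on violation

    def test_scale_distribution_uniform(self):
        """Monte-Carlo: the dilation s follows U[1, min(H,W)/M] (KS, alpha=0.01)."""
        rng = np.random.default_rng(99)
        setup = SourceSetup(det_rows=128, det_cols=128)
        s = np.array([sample_patch_pattern(rng, setup, 32).scale_s for _ in range(10_000)])
        res = stats.kstest(s, stats.uniform(loc=1.0, scale=3.0).cdf)
        assert res.pvalue > 0.01


class TestRays:
    def test_patch_ray_count(self):
        setup = SourceSetup(det_rows=128, det_cols=128)
        pat = PatchPattern(center_uv=(63.5, 63.5), scale_s=2.0, size_m=32)
        assert len(rays_for_patch(setup, Pose(), pat)) == 1024

    def test_central_ray_hits_origin(self):
        setup = SourceSetup(det_rows=3, det_cols=3)
        r = rays_for_detector(setup, Pose(theta_deg=37.0))[4]
        t = -np.dot(r.origin_mm, r.direction)
        assert np.linalg.norm(r.origin_mm + t * r.direction) < 1e-6

    def test_opposed_views_antiparallel(self):
        setup = SourceSetup(det_rows=3, det_cols=3)
        r0 = rays_for_detector(setup, Pose(20.0))[4]
        r1 = rays_for_detector(setup, Pose(200.0))[4]
        assert abs(np.dot(r0.direction, r1.direction) + 1.0) < 1e-9

    def test_detector_ray_count_and_unit_norm(self):
        setup = SourceSetup(det_rows=128, det_cols=128)
        rays = rays_for_detector(setup, Pose(45.0))
        assert len(rays) == 16384
        norms = np.linalg.norm(rays.directions, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-9

    def test_single_pixel_detector(self):
        rays = rays_for_detector(SourceSetup(det_rows=1, det_cols=1), Pose())
        assert len(rays) == 1
        t = -np.dot(rays[0].origin_mm, rays[0].direction)
        assert np.linalg.norm(rays[0].origin_mm + t * rays[0].direction) < 1e-9

    def test_cone_beam_common_origin(self):
        rays = rays_for_detector(SourceSetup(det_rows=4, det_cols=4), Pose(111.0))
        assert np.ptp(rays.origins, axis=0).max() == 0.0

    def test_patch_covering_full_detector_matches(self):
        setup = SourceSetup(det_rows=8, det_cols=8)
        pat = PatchPattern(center_uv=(3.5, 3.5), scale_s=1.0, size_m=8)
        rp = rays_for_patch(setup, Pose(30.0), pat)
        rd = rays_for_detector(setup, Pose(30.0))
        assert np.allclose(rp.directions, rd.directions, atol=1e-12)
        assert np.allclose(rp.origins, rd.origins)

    def test_magnification_relation(self):
        """A point at offset x from the isocenter projects to x*(sid/sad) from
        the detector center (checked analytically against the ray geometry)."""
        setup = SourceSetup(sad_mm=570.0, sid_mm=1040.0, det_rows=5, det_cols=5,
                            det_pitch_mm=2.0)
        pose = Pose(0.0)
        src, c, u_ax, v_ax = pose.frame(setup)
        det_center = src + setup.sid_mm * c
        for e in (10.0, 25.0):
            p = np.array([e, 0.0, 0.0])  # in the isocenter plane, along u
            d = p - src
            # intersect with the detector plane (normal c)
            t = np.dot(det_center - src, c) / np.dot(d, c)
            hit = src + t * d
            offset = np.dot(hit - det_center, u_ax / np.linalg.norm(u_ax))
            assert abs(abs(offset) - e * setup.magnification) < 1e-9


class TestStratifiedSampling:
    def test_one_sample_per_bin(self, rng):
        from tomofield.geometry import Ray

        ray = Ray(np.zeros(3), np.array([1.0, 0, 0]), t_near=0.0, t_far=4.0)
        t, dt = stratified_sample(ray, 4, rng)
        assert t.shape == (4,)
        for i, ti in enumerate(t):
            assert i <= ti < i + 1
        assert abs(dt.sum() - 4.0) < 1e-12

    def test_partition_sums_to_interval(self, rng):
        from tomofield.geometry import Ray

        ray = Ray(np.zeros(3), np.array([0, 1.0, 0]), t_near=3.7, t_far=19.3)
        _, dt = stratified_sample(ray, 13, rng)
        assert abs(dt.sum() - (19.3 - 3.7)) < 1e-9

    def test_single_bin(self, rng):
        from tomofield.geometry import Ray

        ray = Ray(np.zeros(3), np.array([0, 0, 1.0]), t_near=2.0, t_far=5.0)
        t, dt = stratified_sample(ray, 1, rng)
        assert 2.0 <= t[0] < 5.0 and dt[0] == pytest.approx(3.0)

    def test_empty_interval_ray(self, rng):
        from tomofield.geometry import Ray

        ray = Ray(np.zeros(3), np.array([1.0, 0, 0]), t_near=0.0, t_far=0.0, valid=False)
        t, dt = stratified_sample(ray, 8, rng)
        assert t.size == 0 and dt.size == 0

    def test_invalid_q(self, rng):
        from tomofield.geometry import Ray

        ray = Ray(np.zeros(3), np.array([1.0, 0, 0]), 0.0, 1.0)
        with pytest.raises(ValueError):
            stratified_sample(ray, 0, rng)
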