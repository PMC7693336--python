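import numpy as np
import pytest

from vesselflow.core import Movie, Stack
from vesselflow.flow import (
    ArcLengthMap,
    Kymograph,
    Trace2D,
    extract_kymograph,
    flow_trace,
    match_trace_to_3d,
    radon_block_speed,
    reject_segment,
    remap_kymograph_3d,
    segment_diameter,
    skeletonize_stack,
)
from vesselflow.optics import annulus_axial_profile
from vesselflow.scene import SceneConfig, flow_scene, render_bessel_projection, \
    render_gaussian_stack

from conftest import PAPER_SPEC


@pytest.fixture(scope="module")
def profile():
    return annulus_axial_profile(PAPER_SPEC)


def synthetic_streak_kymo(speed_mm_s, dx=3.25, dt=1 / 99, n_rows=100, n_cols=80,
                          spacing=12.0, width=2.0, depth=0.8, noise=0.0, seed=0):
    """Dark streaks on a bright band with known slope (px/row from speed)."""
    rng = np.random.default_rng(seed)
    slope = speed_mm_s * 1000.0 * dt / dx  # px per row
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    data = np.full((n_rows, n_cols), 10.0)
    starts = np.arange(-3 * n_rows * abs(slope) - 40, n_cols + 40, spacing)
    starts = starts + rng.uniform(-0.4, 0.4, starts.size) * spacing  # irregular train
    for c0 in starts:
        center = c0 + slope * rows
        data -= depth * 10.0 * np.exp(-0.5 * ((cols - center) / width) ** 2)
    if noise:
        data += rng.normal(0, noise, data.shape)
    return Kymograph(data, dx=dx, dt=dt)


def flow_phantom_kymo(speed, duration=6.0, seed=1, profile=None):
    cfg = SceneConfig(volume_size=(400.0, 50.0, 60.0), pixel_size=3.25,
                      frame_rate=99.0, duration=duration, n_pial=0,
                      n_penetrating=0, n_capillaries=0, noise_photons=20.0,
                      rbc_spacing=40.0, seed=seed)
    net, truth = flow_scene(speed, cfg)
    movie = render_bessel_projection(net, truth, profile, cfg)
    trace = Trace2D(points=net.segments[0].centerline[:, :2] / cfg.pixel_size)
    return extract_kymograph(movie, trace), cfg


class TestExtractKymograph:
    def test_static_line_constant_columns(self):
        data = np.zeros((8, 20, 30))
        data[:, 10, :] = 5.0
        movie = Movie(data, 1.0, 0.1)
        kymo = extract_kymograph(movie, Trace2D(points=[[2, 10], [27, 10]]))
        np.testing.assert_allclose(kymo.data, 5.0)
        assert kymo.data.shape == (8, 26)

    def test_width_formula(self):
        movie = Movie(np.zeros((2, 40, 40)), 1.0, 0.1)
        trace = Trace2D(points=[[3.0, 5.0], [30.0, 21.0]])
        kymo = extract_kymograph(movie, trace)
        arc = np.hypot(27.0, 16.0)
        assert kymo.data.shape[1] == round(arc) + 1

    def test_streak_slope_matches_speed(self, profile):
        # oracle: least-squares slope of the shadow centroid per frame
        cfg = SceneConfig(volume_size=(300.0, 40.0, 60.0), pixel_size=2.0,
                          frame_rate=99.0, duration=0.25, n_pial=0,
                          n_penetrating=0, n_capillaries=0, noise_photons=0.0,
                          rbc_spacing=1e4, seed=2)  # a single RBC, no wrap
        v = 1.0
        net, truth = flow_scene(v, cfg)
        truth.rbc_offsets[0] = np.array([30.0])
        movie = render_bessel_projection(net, truth, profile, cfg)
        trace = Trace2D(points=net.segments[0].centerline[:, :2] / cfg.pixel_size)
        kymo = extract_kymograph(movie, trace)
        profile_mean = kymo.data.mean(axis=0)
        shadow = profile_mean[None, :] - kymo.data  # positive at the shadow
        centroids = []
        usable = []
        for r in range(kymo.data.shape[0]):
            w = np.clip(shadow[r], 0, None)
            if w.sum() > 1e-6 and w.argmax() not in (0, kymo.data.shape[1] - 1):
                centroids.append((w * np.arange(w.size)).sum() / w.sum())
                usable.append(r)
        slope_px = np.polyfit(usable, centroids, 1)[0]
        v_est = slope_px * kymo.dx / kymo.dt / 1000.0
        assert v_est == pytest.approx(v, rel=0.05)

    def test_trace_outside_rejected(self):
        movie = Movie(np.zeros((2, 10, 10)), 1.0, 0.1)
        with pytest.raises(ValueError):
            extract_kymograph(movie, Trace2D(points=[[0, 0], [50, 0]]))


class TestSkeletonizeStack:
    @staticmethod
    def _tube_stack(p0, p1, radius=3.0, shape=(40, 40, 60), spacing=(1.0, 1.0)):
        z = np.arange(shape[0]) * spacing[1]
        y = (np.arange(shape[1]) + 0.5) * spacing[0]
        x = (np.arange(shape[2]) + 0.5) * spacing[0]
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        d = p1 - p0
        L = np.linalg.norm(d)
        u = d / L
        px = np.stack([xx - p0[0], yy - p0[1], zz - p0[2]])
        t = np.clip(px[0] * u[0] + px[1] * u[1] + px[2] * u[2], 0, L)
        dist2 = ((px[0] - t * u[0]) ** 2 + (px[1] - t * u[1]) ** 2
                 + (px[2] - t * u[2]) ** 2)
        data = (dist2 <= radius ** 2).astype(float)
        return Stack(data, pixel_size=spacing[0], z_step=spacing[1])

    def test_straight_tube_centerline(self):
        stack = self._tube_stack([5, 20, 20], [55, 20, 20])
        sk = skeletonize_stack(stack, 0.5)
        trunk = max(sk.paths, key=len)
        # centerline within 1 voxel of the true axis
        assert np.abs(trunk[:, 1] - 19.5).max() <= 1.0
        assert np.abs(trunk[:, 0] - 20.0).max() <= 1.0
        length = np.linalg.norm(np.diff(trunk, axis=0), axis=1).sum()
        assert length == pytest.approx(50.0, rel=0.15)

    def test_two_endpoints(self):
        stack = self._tube_stack([5, 20, 20], [55, 20, 20])
        sk = skeletonize_stack(stack, 0.5)
        endpoints = [n for n in sk.graph if sk.graph.degree(n) == 1]
        assert len(endpoints) == 2

    def test_skeleton_inside_foreground(self):
        stack = self._tube_stack([5, 20, 20], [55, 20, 20])
        sk = skeletonize_stack(stack, 0.5)
        binary = stack.data >= 0.5
        for z, y, x in np.asarray(sk.voxels, dtype=int):
            assert binary[z, y, x]

    def test_empty_foreground_rejected(self):
        stack = Stack(np.zeros((5, 5, 5)), 1.0, 1.0)
        with pytest.raises(ValueError):
            skeletonize_stack(stack, 0.5)


class TestMatchTraceTo3D:
    def test_in_plane_identity(self):
        stack = TestSkeletonizeStack._tube_stack([5, 20, 20], [55, 20, 20])
        sk = skeletonize_stack(stack, 0.5)
        trace = Trace2D(points=[[8.0, 19.5], [52.0, 19.5]])
        amap = match_trace_to_3d(trace, sk, pixel_size=1.0, z_step=1.0)
        np.testing.assert_allclose(amap.u, amap.s, atol=1.5)

    def test_45_degree_descent_sqrt2(self):
        stack = TestSkeletonizeStack._tube_stack([10, 20, 5], [50, 20, 45],
                                                 shape=(50, 40, 60))
        sk = skeletonize_stack(stack, 0.5)
        trace = Trace2D(points=[[12.0, 19.5], [48.0, 19.5]])
        amap = match_trace_to_3d(trace, sk, pixel_size=1.0, z_step=1.0)
        ratio = amap.total_3d_length / amap.total_2d_length
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_monotone_and_anchored(self):
        stack = TestSkeletonizeStack._tube_stack([10, 20, 5], [50, 20, 45],
                                                 shape=(50, 40, 60))
        sk = skeletonize_stack(stack, 0.5)
        trace = Trace2D(points=[[12.0, 19.5], [48.0, 19.5]])
        amap = match_trace_to_3d(trace, sk, pixel_size=1.0, z_step=1.0)
        assert amap.u[0] == 0.0
        assert np.all(np.diff(amap.u) >= 0)
        assert amap.total_3d_length >= amap.total_2d_length - 1e-9

    def test_helix_length_within_3_percent(self):
        # half-turn helical capillary; analytic length = pi*sqrt(R^2 + (H/pi)^2)
        R, H = 10.0, 24.0
        theta = np.linspace(0, np.pi, 120)
        cx, cy = 20.0, 20.0
        xs = cx + R * np.cos(theta)
        ys = cy + R * np.sin(theta)
        zs = 8.0 + H * theta / np.pi
        shape = (40, 44, 44)
        zz, yy, xx = np.meshgrid(np.arange(shape[0], dtype=float),
                                 (np.arange(shape[1]) + 0.5),
                                 (np.arange(shape[2]) + 0.5), indexing="ij")
        data = np.zeros(shape)
        for x0, y0, z0 in zip(xs, ys, zs):
            data = np.maximum(
                data, ((xx - x0) ** 2 + (yy - y0) ** 2 + (zz - z0) ** 2 <= 2.5 ** 2)
                .astype(float))
        stack = Stack(data, pixel_size=1.0, z_step=1.0)
        sk = skeletonize_stack(stack, 0.5)
        pts = np.vstack([np.column_stack([xs, ys])[::6], [xs[-1], ys[-1]]])
        amap = match_trace_to_3d(Trace2D(points=pts), sk, pixel_size=1.0, z_step=1.0)
        analytic = np.pi * np.hypot(R, H / np.pi)
        assert amap.total_3d_length == pytest.approx(analytic, rel=0.03)

    def test_far_trace_rejected(self):
        stack = TestSkeletonizeStack._tube_stack([5, 20, 20], [55, 20, 20])
        sk = skeletonize_stack(stack, 0.5)
        trace = Trace2D(points=[[8.0, 5.0], [52.0, 5.0]])
        with pytest.raises(ValueError):
            match_trace_to_3d(trace, sk, pixel_size=1.0, z_step=1.0)


class TestRemapKymograph:
    def test_identity_map_unchanged(self, rng):
        data = rng.uniform(0, 1, (60, 30))
        kymo = Kymograph(data, dx=2.0, dt=0.01)
        s = np.arange(30) * 2.0
        amap = ArcLengthMap(s=s, u=s.copy())
        out = remap_kymograph_3d(kymo, amap)
        np.testing.assert_allclose(out.data, data, atol=1e-6)

    def test_sqrt2_stretch_recovers_speed(self):
        # 45-degree streaks: apparent speed v/sqrt(2) becomes v after remap
        kymo = synthetic_streak_kymo(1.0 / np.sqrt(2), n_cols=40)
        s = np.arange(40) * kymo.dx
        amap = ArcLengthMap(s=s, u=s * np.sqrt(2))
        out = remap_kymograph_3d(kymo, amap)
        v = radon_block_speed(out.data[:50], out.dx, out.dt)
        assert v == pytest.approx(1.0, rel=0.05)

    def test_row_mass_preserved(self, rng):
        data = rng.uniform(1, 2, (10, 50))
        kymo = Kymograph(data, dx=1.0, dt=0.01)
        s = np.arange(50) * 1.0
        amap = ArcLengthMap(s=s, u=s * 1.3)
        out = remap_kymograph_3d(kymo, amap)
        # mean per row is conserved within interpolation error
        np.testing.assert_allclose(out.data.mean(axis=1), data.mean(axis=1),
                                   rtol=0.02)

    def test_non_monotone_rejected(self):
        kymo = Kymograph(np.zeros((5, 10)), dx=1.0, dt=0.01)
        s = np.arange(10) * 1.0
        u = s.copy()
        u[5] = u[4] - 1.0
        with pytest.raises(ValueError):
            remap_kymograph_3d(kymo, ArcLengthMap(s=s, u=u))


class TestRadonBlockSpeed:
    def test_known_slope_one(self):
        kymo = synthetic_streak_kymo(1.0)
        v = radon_block_speed(kymo.data[:50], kymo.dx, kymo.dt)
        assert v == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("speed", [0.5, 2.0, -1.0])
    def test_known_slopes(self, speed):
        kymo = synthetic_streak_kymo(speed, noise=0.3)
        v = radon_block_speed(kymo.data[:50], kymo.dx, kymo.dt)
        assert v == pytest.approx(speed, rel=0.1)

    def test_stationary_shadows_zero(self):
        kymo = synthetic_streak_kymo(0.0)
        v = radon_block_speed(kymo.data[:50], kymo.dx, kymo.dt)
        assert v == 0.0

    def test_mirror_flip_negates(self):
        kymo = synthetic_streak_kymo(1.5, noise=0.2)
        v = radon_block_speed(kymo.data[:50], kymo.dx, kymo.dt)
        v_flip = radon_block_speed(kymo.data[:50, ::-1], kymo.dx, kymo.dt)
        assert v_flip == pytest.approx(-v, rel=0.02)

    def test_featureless_block_nan(self):
        v = radon_block_speed(np.zeros((50, 20)), 1.0, 0.01)
        assert np.isnan(v)

    def test_noise_only_block_nan(self, rng):
        block = rng.poisson(30, (50, 30)).astype(float)
        v = radon_block_speed(block, 1.0, 0.01)
        assert np.isnan(v)

    def test_agrees_with_centroid_oracle(self):
        # brute-force oracle: least-squares line fit to the per-row
        # centroids of two clean streaks staying inside the block
        dx, dt = 3.25, 1 / 99
        slope_px = 0.9  # px/row
        rows = np.arange(50)[:, None]
        cols = np.arange(80)[None, :]
        block = np.full((50, 80), 10.0)
        for c0 in (8.0, 28.0):
            center = c0 + slope_px * rows
            block -= 8.0 * np.exp(-0.5 * ((cols - center) / 2.0) ** 2)
        v = radon_block_speed(block, dx, dt)
        shadow = 10.0 - block
        cs = [(shadow[r] * cols[0]).sum() / shadow[r].sum() for r in range(50)]
        fit = np.polyfit(np.arange(50), cs, 1)[0]
        oracle = fit * dx / dt / 1000.0
        assert oracle == pytest.approx(slope_px * dx / dt / 1000.0, rel=0.01)
        assert v == pytest.approx(oracle, rel=0.05)

    def test_short_block_rejected(self):
        with pytest.raises(ValueError):
            radon_block_speed(np.zeros((30, 20)), 1.0, 0.01)

    def test_narrow_block_rejected(self):
        with pytest.raises(ValueError):
            radon_block_speed(np.zeros((50, 4)), 1.0, 0.01)


class TestFlowTrace:
    def test_constant_speed_phantom(self, profile):
        kymo, _ = flow_phantom_kymo(2.0, duration=3.0, profile=profile)
        result = flow_trace(kymo)
        assert result.block_speeds.size == kymo.data.shape[0] // 50
        assert result.median_speed == pytest.approx(2.0, abs=0.2)
        assert not result.rejected

    def test_all_flat_rejected(self):
        kymo = Kymograph(np.zeros((200, 30)), dx=1.0, dt=0.01)
        result = flow_trace(kymo)
        assert result.rejected
        assert np.isnan(result.block_speeds).all()

    def test_block_count(self):
        kymo = Kymograph(np.zeros((230, 30)), dx=1.0, dt=0.01)
        result = flow_trace(kymo)
        assert result.block_speeds.size == 4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            flow_trace(Kymograph(np.zeros((20, 30)), 1.0, 0.01))


class TestRejectSegment:
    def test_all_good_kept(self):
        rejected, _ = reject_segment(np.full(30, 1.0))
        assert not rejected

    def test_forty_percent_outliers_rejected(self):
        speeds = np.concatenate([np.full(12, 6.0), np.full(18, 1.0)])
        rejected, reason = reject_segment(speeds)
        assert rejected

    def test_exactly_one_third_kept(self):
        # strict inequality at the boundary
        speeds = np.concatenate([np.full(10, 6.0), np.full(20, 1.0)])
        rejected, _ = reject_segment(speeds)
        assert not rejected

    def test_just_above_one_third_rejected(self):
        speeds = np.concatenate([np.full(11, 6.0), np.full(19, 1.0)])
        rejected, _ = reject_segment(speeds)
        assert rejected

    def test_reversed_flow_counts_as_outlier(self):
        speeds = np.concatenate([np.full(11, -0.5), np.full(19, 1.0)])
        rejected, _ = reject_segment(speeds)
        assert rejected

    def test_mostly_flat_rejected(self):
        speeds = np.full(30, np.nan)
        speeds[:9] = 1.0
        rejected, reason = reject_segment(speeds)
        assert rejected
        assert "streak" in reason

    def test_no_blocks_rejected(self):
        rejected, _ = reject_segment(np.array([]))
        assert rejected


class TestSegmentDiameter:
    def test_noiseless_cylinder(self, profile):
        cfg = SceneConfig(volume_size=(60.0, 40.0, 60.0), pixel_size=0.5,
                          frame_rate=15.0, duration=1 / 15, n_pial=0,
                          n_penetrating=0, n_capillaries=0, noise_photons=0.0,
                          background=0.1, seed=0)
        from vesselflow.scene import cylinder_scene

        net, truth = cylinder_scene(10.0, cfg)
        movie = render_bessel_projection(net, truth, profile, cfg)
        img = movie.data[0]
        d = segment_diameter(img, ((60.0, 15.0), (60.0, 65.0)), cfg.pixel_size)
        # FWHM of the chord profile is 0.866 d for an ideal cylinder
        assert d == pytest.approx(0.866 * 10.0, abs=1.0)

    def test_intensity_gain_invariant(self, profile):
        rngimg = np.zeros((40, 40))
        yy = np.arange(40)
        rngimg[:, :] = np.exp(-0.5 * ((yy[:, None] - 20) / 3.0) ** 2)
        d1 = segment_diameter(rngimg, ((20.0, 5.0), (20.0, 35.0)), 1.0)
        d2 = segment_diameter(5.0 * rngimg, ((20.0, 5.0), (20.0, 35.0)), 1.0)
        assert d1 == pytest.approx(d2)

    def test_background_only_rejected(self):
        with pytest.raises(ValueError):
            segment_diameter(np.ones((20, 20)), ((2.0, 2.0), (2.0, 18.0)), 1.0)


class TestEndToEnd3D:
    def test_45_degree_recovery_with_remap(self, profile):
        cfg = SceneConfig(volume_size=(110.0, 50.0, 64.0), pixel_size=2.0,
                          frame_rate=99.0, duration=10.0, n_pial=0,
                          n_penetrating=0, n_capillaries=0, noise_photons=20.0,
                          rbc_spacing=20.0, seed=1)
        v = 1.0
        net, truth = flow_scene(v, cfg, orientation="descending_45")
        movie = render_bessel_projection(net, truth, profile, cfg)
        trace = Trace2D(points=net.segments[0].centerline[:, :2] / cfg.pixel_size)
        kymo = extract_kymograph(movie, trace)
        stack = render_gaussian_stack(net, truth, cfg, z_step=2.0)
        sk = skeletonize_stack(stack, 0.5 * stack.data.max())
        amap = match_trace_to_3d(trace, sk, cfg.pixel_size, 2.0)
        assert amap.total_3d_length / amap.total_2d_length == pytest.approx(
            np.sqrt(2), rel=0.1)
        result = flow_trace(remap_kymograph_3d(kymo, amap))
        assert result.median_speed == pytest.approx(v, rel=0.1)
        assert not result.rejected
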