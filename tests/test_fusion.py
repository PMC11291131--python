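"""Surface extraction, MSAC/ICP registration and intensity fusion."""

import numpy as np
import pytest

from chambervol import rasterize_views
from chambervol.containers import PointCloud, RigidTransform, VoxelVolume
from chambervol.fusion import (
    compose_to_common_frame,
    estimate_rigid_transform_msac,
    extract_outer_surface,
    fuse_volumes,
    refine_icp,
)


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0], [0, 0, 1]])


def _sphere_volume(n=64, spacing_um=40.0, radius=1.0, center=None):
    sp = np.full(3, spacing_um)
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    pts = np.stack([ii, jj, kk], -1) * spacing_um / 1000.0
    c = center if center is not None else np.full(3, n * spacing_um / 2000.0)
    d = np.linalg.norm(pts - c, axis=-1)
    return VoxelVolume((d < radius).astype(np.float32), sp), c


class TestExtractOuterSurface:
    def test_sphere_surface_at_radius(self):
        vol, c = _sphere_volume()
        cloud = extract_outer_surface(vol, 0.5)
        d = np.linalg.norm(cloud.points - c, axis=1)
        diag = np.linalg.norm(vol.spacing_mm)
        assert d.min() > 1.0 - diag and d.max() < 1.0 + diag

    def test_largest_component_kept(self):
        arr = np.zeros((40, 40, 40), dtype=np.float32)
        arr[5:15, 5:15, 5:15] = 1.0      # 1000 voxels
        arr[30:32, 30:32, 30:33] = 1.0   # 12 voxels
        vol = VoxelVolume(arr, np.full(3, 10.0))
        cloud = extract_outer_surface(vol, 0.5)
        assert np.all(cloud.points.max(axis=0) < 0.20)

    def test_all_zero_volume_rejected(self):
        vol = VoxelVolume(np.zeros((8, 8, 8), dtype=np.float32), np.ones(3))
        with pytest.raises(ValueError, match="threshold|object"):
            extract_outer_surface(vol, 0.5)


class TestMsac:
    def test_identity_for_identical_sets(self, rng):
        pts = rng.uniform(-1, 1, (15, 3))
        tf, inl = estimate_rigid_transform_msac(pts, pts, inlier_tol=1e-6, seed=0)
        assert inl.all()
        assert np.allclose(tf.matrix(), np.eye(4), atol=1e-12)

    def test_exact_recovery_of_constructed_transform(self, rng):
        src = rng.uniform(-1, 1, (15, 3))
        truth = RigidTransform(_rot_z(45.0), np.array([0.3, -0.2, 0.1]))
        tf, _ = estimate_rigid_transform_msac(src, truth.apply(src),
                                              inlier_tol=1e-6, seed=0)
        assert np.abs(tf.matrix() - truth.matrix()).max() < 1e-9

    def test_robust_to_outliers_and_jitter(self, rng):
        """One third of the correspondences replaced by gross mispicks."""
        src = rng.uniform(0, 2, (15, 3))
        truth = RigidTransform(_rot_z(45.0), np.array([0.1, 0.05, -0.2]))
        dst = truth.apply(src) + rng.normal(0, 1e-3, (15, 3))  # 1 µm jitter
        bad = rng.choice(15, 5, replace=False)
        dst[bad] = rng.uniform(0, 2, (5, 3))
        tf, inl = estimate_rigid_transform_msac(src, dst, inlier_tol=0.01,
                                                seed=2)
        delta = tf.compose(truth.inverse())
        assert delta.rotation_angle_deg() < 0.1
        assert not inl[bad].any()

    def test_equivariance_under_pre_rotation(self, rng):
        """Rotating both landmark sets conjugates the recovered transform."""
        src = rng.uniform(-1, 1, (15, 3))
        truth = RigidTransform(_rot_z(30.0), np.array([0.2, 0.0, -0.1]))
        dst = truth.apply(src)
        q = RigidTransform(_rot_z(77.0), np.zeros(3))
        tf1, _ = estimate_rigid_transform_msac(src, dst, inlier_tol=1e-6, seed=0)
        tf2, _ = estimate_rigid_transform_msac(q.apply(src), q.apply(dst),
                                               inlier_tol=1e-6, seed=0)
        conj = q.compose(tf1).compose(q.inverse())
        assert np.abs(tf2.matrix() - conj.matrix()).max() < 1e-8

    def test_too_few_or_collinear_points_rejected(self, rng):
        pts = rng.uniform(-1, 1, (2, 3))
        with pytest.raises(ValueError):
            estimate_rigid_transform_msac(pts, pts, inlier_tol=0.1)
        line = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            estimate_rigid_transform_msac(line, line, inlier_tol=0.1)


class TestIcp:
    @staticmethod
    def _shell_cloud(rng, n=3000):
        """Non-symmetric bumpy shell so ICP has full pose information."""
        th = np.arccos(rng.uniform(-1, 1, n))
        ph = rng.uniform(0, 2 * np.pi, n)
        r = 1.0 + 0.15 * np.sin(3 * th) * np.cos(2 * ph)
        return np.column_stack([r * np.sin(th) * np.cos(ph),
                                r * np.sin(th) * np.sin(ph),
                                r * np.cos(th)])

    def test_truth_is_fixed_point(self, rng):
        pts = self._shell_cloud(rng)
        truth = RigidTransform(_rot_z(20.0), np.array([0.1, 0.2, 0.0]))
        tf = refine_icp(PointCloud(pts), PointCloud(truth.apply(pts)), truth)
        assert tf.compose(truth.inverse()).rotation_angle_deg() < 1e-6

    def test_converges_from_perturbed_init(self, rng):
        pts = self._shell_cloud(rng)
        truth = RigidTransform(_rot_z(10.0), np.array([0.05, -0.1, 0.2]))
        init = RigidTransform(_rot_z(12.0), truth.translation + 0.02)
        tf = refine_icp(PointCloud(pts), PointCloud(truth.apply(pts)), init,
                        max_iter=100, tol=1e-9)
        delta = tf.compose(truth.inverse())
        assert delta.rotation_angle_deg() < 0.2
        assert np.linalg.norm(tf.translation - truth.translation) < 0.005

    def test_disjoint_clouds_rejected(self, rng):
        a = rng.uniform(0, 1, (200, 3))
        b = rng.uniform(50, 51, (200, 3))
        with pytest.raises(ValueError, match="overlap"):
            refine_icp(PointCloud(a), PointCloud(b), RigidTransform.identity())


class TestCompose:
    def test_identity_chain(self):
        out = compose_to_common_frame([RigidTransform.identity()] * 7)
        assert len(out) == 8
        for tf in out:
            assert np.allclose(tf.matrix(), np.eye(4))

    def test_eight_view_ring_midpoint_is_half_turn(self):
        pairwise = [RigidTransform(_rot_z(45.0), np.zeros(3)) for _ in range(7)]
        out = compose_to_common_frame(pairwise)
        assert np.allclose(out[4].rotation, _rot_z(180.0), atol=1e-12)

    def test_single_view(self):
        out = compose_to_common_frame([])
        assert len(out) == 1
        assert np.allclose(out[0].matrix(), np.eye(4))


class TestFuse:
    def test_single_identity_view_is_idempotent(self, rng):
        arr = rng.random((20, 20, 20)).astype(np.float32)
        vol = VoxelVolume(arr, np.full(3, 25.0))
        fused, cov = fuse_volumes([vol], [RigidTransform.identity()],
                                  vol.spacing, out_origin=vol.origin,
                                  out_shape=vol.shape)
        assert np.allclose(fused.intensities, arr, atol=1e-6)
        assert (cov == 1).all()

    def test_two_shifted_copies_match_direct_raster(self):
        vol, c = _sphere_volume(n=48, spacing_um=50.0, radius=0.8)
        shift = RigidTransform(np.eye(3), np.array([0.1, 0.0, 0.0]))
        # view B is the same sphere rasterized in a frame shifted by -0.1 mm
        volB, _ = _sphere_volume(n=48, spacing_um=50.0, radius=0.8,
                                 center=c - shift.translation)
        fused, cov = fuse_volumes([vol, volB],
                                  [RigidTransform.identity(), shift],
                                  vol.spacing, out_origin=np.zeros(3),
                                  out_shape=vol.shape)
        inside = cov == 2
        diff = np.abs(fused.intensities - vol.intensities)[inside]
        assert diff.mean() < 0.02  # mean abs error < 2 % of dynamic range

    def test_empty_view_list_rejected(self):
        with pytest.raises(ValueError):
            fuse_volumes([], [], np.ones(3))


class TestEndToEndRegistration:
    def test_noiseless_transform_recovery(self, default_model):
        """Landmark chain on a noiseless 8-view acquisition recovers the
        true absolute poses to < 0.05 degrees and < 0.5 voxel."""
        acq = rasterize_views(default_model, n_views=8,
                              grid_shape=(48, 48, 48), noise_spec=None, seed=11)
        pairwise = []
        for lm in acq.landmark_sets:
            tol = 3.0 * float(np.mean(acq.views[0].spacing_mm))
            tf, _ = estimate_rigid_transform_msac(lm["src"], lm["dst"],
                                                  inlier_tol=tol, seed=5)
            pairwise.append(tf)
        absolute = compose_to_common_frame(pairwise)
        voxel = float(np.max(acq.views[0].spacing_mm))
        for est, ta, t0 in zip(absolute, acq.true_transforms,
                               [acq.true_transforms[0]] * 8):
            truth = t0.inverse().compose(ta)  # absolute pose in view-0 frame
            delta = est.compose(truth.inverse())
            assert delta.rotation_angle_deg() < 0.05
            assert np.linalg.norm(est.translation - truth.translation) < 0.5 * voxel
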