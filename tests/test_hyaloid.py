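"""Lens-surface extraction, ellipsoid fitting and posterior-mask correction."""

import numpy as np
import pytest

from chambervol.containers import ChamberMask, PointCloud
from chambervol.hyaloid import (
    EllipsoidFit,
    Plane,
    correct_posterior_mask,
    equatorial_plane,
    extract_lens_surface,
    fit_ellipsoid,
)


def _upper_cap_points(center, axes, rng, n=600):
    th = rng.uniform(0.0, 0.5 * np.pi, n)
    ph = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([
        axes[0] * np.sin(th) * np.cos(ph),
        axes[1] * np.sin(th) * np.sin(ph),
        -axes[2] * np.cos(th),
    ]) + center


class TestFitEllipsoid:
    def test_exact_recovery_from_upper_cap(self, rng):
        center = np.array([0.1, -0.2, 1.4])
        axes = np.array([1.2, 1.2, 0.9])
        fit = fit_ellipsoid(PointCloud(_upper_cap_points(center, axes, rng)))
        assert np.abs(fit.center - center).max() < 1e-6
        assert np.abs(fit.semi_axes - axes).max() < 1e-6
        assert fit.rms_residual < 1e-9

    def test_sphere_gives_equal_axes(self, rng):
        fit = fit_ellipsoid(PointCloud(
            _upper_cap_points(np.zeros(3), np.full(3, 0.9), rng)))
        assert np.ptp(fit.semi_axes) < 1e-6

    def test_translation_equivariance(self, rng):
        pts = _upper_cap_points(np.array([0.0, 0.0, 1.0]),
                                np.array([1.1, 1.1, 0.8]), rng)
        shift = np.array([0.3, -0.4, 0.25])
        f1 = fit_ellipsoid(PointCloud(pts))
        f2 = fit_ellipsoid(PointCloud(pts + shift))
        assert np.abs(f2.center - f1.center - shift).max() < 1e-8
        assert np.abs(f2.semi_axes - f1.semi_axes).max() < 1e-8

    def test_coplanar_points_rejected(self, rng):
        pts = rng.uniform(-1, 1, (40, 3))
        pts[:, 2] = 0.7
        with pytest.raises(ValueError, match="ill-conditioned"):
            fit_ellipsoid(PointCloud(pts))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ellipsoid(PointCloud(rng.uniform(-1, 1, (5, 3))))

    def test_trimming_survives_contamination(self, rng):
        """A handful of stray off-surface points does not move the fit."""
        center = np.array([0.0, 0.0, 1.25])
        axes = np.array([1.2, 1.2, 0.9])
        pts = _upper_cap_points(center, axes, rng, n=800)
        junk = rng.uniform([-1.4, -1.4, 0.3], [1.4, 1.4, 2.2], (60, 3))
        fit = fit_ellipsoid(PointCloud(np.vstack([pts, junk])),
                            trim_iterations=3)
        assert np.abs(fit.center - center).max() < 0.01
        assert np.abs(fit.semi_axes - axes).max() < 0.01


class TestEquatorialPlane:
    def _fit(self, cz):
        return EllipsoidFit(center=np.array([0.0, 0.0, cz]),
                            semi_axes=np.array([1.2, 1.2, 0.9]),
                            rms_residual=0.0, n_points=100)

    def test_plane_through_center_origin(self):
        plane = equatorial_plane(self._fit(0.0), (0, 0, 1))
        assert plane.signed_distance(np.array([[0.5, 0.5, 0.0]]))[0] == 0.0

    def test_plane_at_center_height(self):
        plane = equatorial_plane(self._fit(1.4), (0, 0, 1))
        assert plane.point[2] == pytest.approx(1.4)

    def test_axis_normalized(self):
        plane = equatorial_plane(self._fit(1.0), (0, 0, 7.5))
        assert np.linalg.norm(plane.normal) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(plane.normal, [0, 0, 1])

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            equatorial_plane(self._fit(1.0), (0, 0, 0))


class TestExtractLensSurface:
    def test_synthetic_masks_yield_points_near_lens(self, default_model):
        """Boundary points extracted from rasterized truth masks lie on the
        true lens ellipsoid to within ~1.5 voxels RMS."""
        m = default_model
        n = 96
        lo = np.array([-1.7, -1.7, 0.0])
        sp_mm = np.array([3.4 / n, 3.4 / n, 2.2 / n])
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        pts = lo + np.stack([ii, jj, kk], -1) * sp_mm
        flat = pts.reshape(-1, 3)
        ac = ChamberMask(m.ac_region(flat).reshape(n, n, n), "common",
                         "anterior", sp_mm * 1000.0, lo)
        pc = ChamberMask(m.pc_region(flat).reshape(n, n, n), "common",
                         "posterior", sp_mm * 1000.0, lo)
        cloud = extract_lens_surface(ac, pc)
        a, c = m.lens_semi_axes[0], m.lens_semi_axes[2]
        q = np.sqrt((np.hypot(cloud.points[:, 0], cloud.points[:, 1]) / a) ** 2
                    + ((cloud.points[:, 2] - m.lens_center[2]) / c) ** 2)
        # algebraic offset -> approximate distance via the local gradient
        dist = np.abs(q - 1.0) * min(a, c)
        rms = np.sqrt(np.mean(dist**2))
        assert rms < 1.5 * np.max(sp_mm)

    def test_ac_only_with_warning(self, default_model):
        m = default_model
        n = 64
        lo = np.array([-1.7, -1.7, 0.0])
        sp_mm = np.array([3.4 / n, 3.4 / n, 2.2 / n])
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        flat = (lo + np.stack([ii, jj, kk], -1) * sp_mm).reshape(-1, 3)
        ac = ChamberMask(m.ac_region(flat).reshape(n, n, n), "common",
                         "anterior", sp_mm * 1000.0, lo)
        pc = ChamberMask(np.zeros((n, n, n), dtype=bool), "common",
                         "posterior", sp_mm * 1000.0, lo)
        with pytest.warns(UserWarning, match="empty"):
            cloud = extract_lens_surface(ac, pc)
        assert len(cloud) > 0

    def test_overlapping_masks_rejected(self):
        arr = np.zeros((8, 8, 8), dtype=bool)
        arr[2:6, 2:6, 2:6] = True
        ac = ChamberMask(arr, "common", "anterior", np.full(3, 20.0))
        pc = ChamberMask(arr, "common", "posterior", np.full(3, 20.0))
        with pytest.raises(ValueError, match="overlap"):
            extract_lens_surface(ac, pc)


class TestCorrectPosteriorMask:
    @staticmethod
    def _ball_mask(n=64, sp=30.0, radius=0.8, cut_z=None):
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        pts = np.stack([ii, jj, kk], -1) * sp / 1000.0
        c = np.full(3, n * sp / 2000.0)
        ball = np.linalg.norm(pts - c, axis=-1) < radius
        if cut_z is not None:
            ball &= pts[..., 2] <= cut_z
        return ChamberMask(ball, "common", "posterior", np.full(3, sp)), c

    @staticmethod
    def _far_lens():
        # a lens placed outside the mask so it does not carve anything
        return EllipsoidFit(center=np.array([5.0, 5.0, 5.0]),
                            semi_axes=np.array([0.1, 0.1, 0.1]),
                            rms_residual=0.0, n_points=100)

    def _boundary_cloud(self, mask):
        from chambervol.pipeline import pc_outer_boundary
        return pc_outer_boundary(mask, axis_xy=np.array([
            mask.mask.shape[0] * mask.spacing_mm[0] / 2.0,
            mask.mask.shape[1] * mask.spacing_mm[1] / 2.0]))

    def test_plane_at_posterior_extreme_is_fixed_point(self):
        # a chamber-like ring with a straight (pars-plana-like) outer wall,
        # already reaching the plane: nothing to fill, nothing to cut
        n, sp = 64, 30.0
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        pts = np.stack([ii, jj, kk], -1) * sp / 1000.0
        c = np.full(3, n * sp / 2000.0)
        r = np.hypot(pts[..., 0] - c[0], pts[..., 1] - c[1])
        # inner bound: a tall "lens" filling the ring's core; the ring is its
        # exact complement so the geometry is self-consistent
        # semi-axis chosen off the voxel-radius lattice so no voxel center
        # sits exactly on the surface (floating-point tie)
        lens = EllipsoidFit(center=np.array([c[0], c[1], 0.75]),
                            semi_axes=np.array([0.3001, 0.3001, 5.0]),
                            rms_residual=0.0, n_points=100)
        ring = (~lens.contains(pts)) & (r < 0.7) \
            & (pts[..., 2] >= 0.4) & (pts[..., 2] <= 1.1)
        mask = ChamberMask(ring, "common", "posterior", np.full(3, sp))
        plane = Plane(np.array([c[0], c[1], 1.1]), np.array([0, 0, 1.0]))
        # outer boundary cloud taken directly from the mask's outermost voxels
        coords = mask.voxel_coords_mm()
        rr = np.hypot(coords[:, 0] - c[0], coords[:, 1] - c[1])
        wall = PointCloud(coords[rr > rr.max() - 1e-9])
        out = correct_posterior_mask(mask, plane, lens, wall)
        assert out.voxel_count() == mask.voxel_count()

    def test_mask_past_plane_is_truncated(self):
        mask, c = self._ball_mask()
        plane = Plane(c, np.array([0, 0, 1.0]))  # plane through the center
        out = correct_posterior_mask(mask, plane, self._far_lens(),
                                     self._boundary_cloud(mask))
        coords = out.voxel_coords_mm()
        assert np.all(plane.signed_distance(coords) <= 1e-9)
        assert out.voxel_count() < mask.voxel_count()

    def test_no_voxels_posterior_or_inside_lens(self, default_model, rng):
        """Invariant: the corrected mask stays anterior of the plane and
        outside the fitted lens."""
        from chambervol.pipeline import measure_single_volume
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            r = measure_single_volume(default_model, grid=80,
                                      noise_spec=None, seed=0)
        pc, fit = r["pc_mask"], r["lens_fit"]
        coords = pc.voxel_coords_mm()
        assert np.all(coords[:, 2] <= fit.center[2] + 1e-9)
        assert not fit.contains(coords).any()

    def test_plane_outside_grid_rejected(self):
        mask, c = self._ball_mask()
        plane = Plane(np.array([c[0], c[1], 99.0]), np.array([0, 0, 1.0]))
        with pytest.raises(ValueError, match="outside"):
            correct_posterior_mask(mask, plane, self._far_lens(),
                                   self._boundary_cloud(mask))
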