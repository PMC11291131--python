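"""Seed interpolation, seeded region growing and mask merging."""

import warnings

import numpy as np
import pytest

from chambervol.containers import ChamberMask, RigidTransform, VoxelVolume
from chambervol.segmentation import (
    SeedSet,
    interpolate_seeds,
    merge_masks,
    segment_chamber,
)


def _seed_rows(track, bscans, x_fn, z_fn):
    return np.array([(track, b, x_fn(b), z_fn(b)) for b in bscans], dtype=float)


class TestInterpolateSeeds:
    def test_exact_on_cubic_trajectory(self):
        """Sparse picks every 50 B-scans on a cubic path reproduce it exactly."""
        poly_x = lambda b: 1e-6 * b**3 - 2e-4 * b**2 + 0.05 * b + 40
        poly_z = lambda b: -5e-7 * b**3 + 1e-4 * b**2 - 0.02 * b + 80
        sparse = SeedSet(_seed_rows(0, range(0, 512, 50), poly_x, poly_z))
        dense = interpolate_seeds(sparse, 512)
        for _, b, x, z in dense.inlier_points:
            assert x == pytest.approx(poly_x(b), abs=1e-9)
            assert z == pytest.approx(poly_z(b), abs=1e-9)

    def test_constant_track_stays_constant(self):
        sparse = SeedSet(_seed_rows(0, range(0, 200, 50),
                                    lambda b: 33.0, lambda b: 77.0))
        dense = interpolate_seeds(sparse, 200)
        assert np.allclose(dense.inlier_points[:, 2], 33.0)
        assert np.allclose(dense.inlier_points[:, 3], 77.0)

    def test_sine_trajectory_error_below_growing_tolerance(self):
        """Cubic fit of a gentle sinusoid stays within a few voxels."""
        x_fn = lambda b: 60 + 10 * np.sin(b / 512 * np.pi)
        sparse = SeedSet(_seed_rows(0, range(0, 512, 50), x_fn, lambda b: 50.0))
        dense = interpolate_seeds(sparse, 512)
        err = np.abs(dense.inlier_points[:, 2]
                     - x_fn(dense.inlier_points[:, 1]))
        assert err.max() < 2.0

    def test_too_few_support_bscans_rejected(self):
        sparse = SeedSet(_seed_rows(0, [0, 50, 100], lambda b: 1, lambda b: 1))
        with pytest.raises(ValueError, match="4 seeded B-scans"):
            interpolate_seeds(sparse, 512)


def _ring_volume(n=64, r_in=0.25, r_out=0.45):
    """Dark annulus enclosed by a bright ring in every B-scan."""
    sp = 20.0
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    x = (ii - n / 2) * sp / 1000.0
    z = (kk - n / 2) * sp / 1000.0
    r = np.hypot(x, z)
    arr = np.full((n, n, n), 0.02, dtype=np.float32)
    arr[(r >= r_in - 0.04) & (r <= r_in)] = 1.0
    arr[(r >= r_out) & (r <= r_out + 0.04)] = 1.0
    truth = (r > r_in) & (r < r_out)
    return VoxelVolume(arr, np.full(3, sp)), truth


class TestSegmentChamber:
    BAND = (0.0, 0.45)

    def test_enclosed_dark_region_high_dice(self):
        vol, truth = _ring_volume()
        n = vol.shape[0]
        seeds = SeedSet(_seed_rows(0, list(range(0, n, 8)) + [n - 1],
                                   lambda b: n / 2 + 0.35 / 0.02,
                                   lambda b: n / 2))
        dense = interpolate_seeds(seeds, n)
        mask = segment_chamber(vol, dense, self.BAND, "posterior")
        inter = (mask.mask & truth).sum()
        dice = 2 * inter / (mask.mask.sum() + truth.sum())
        assert dice >= 0.97

    def test_outlier_seed_excludes_region(self):
        vol, _ = _ring_volume()
        n = vol.shape[0]
        x_ring = n / 2 + 0.35 / 0.02
        inl = _seed_rows(0, range(0, n, 8), lambda b: x_ring, lambda b: n / 2)
        outl = _seed_rows(9, range(0, n, 8), lambda b: x_ring + 1,
                          lambda b: n / 2)
        dense = interpolate_seeds(SeedSet(inl, outl), n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = segment_chamber(vol, dense, self.BAND, "posterior")
        assert mask.voxel_count() == 0

    def test_uniform_volume_floods_whole_slice(self):
        """No boundaries: the failure mode is a full-slice mask."""
        vol = VoxelVolume(np.full((16, 16, 16), 0.1, dtype=np.float32),
                          np.full(3, 10.0))
        seeds = interpolate_seeds(
            SeedSet(_seed_rows(0, range(0, 16, 4), lambda b: 8, lambda b: 8)), 16)
        mask = segment_chamber(vol, seeds, self.BAND, "anterior")
        for b in range(0, 16, 4):
            assert mask.mask[:, b, :].all()

    def test_seed_on_boundary_raises_in_strict_mode(self):
        vol, _ = _ring_volume()
        n = vol.shape[0]
        x_bright = n / 2 + 0.25 / 0.02  # on the inner bright ring
        seeds = interpolate_seeds(
            SeedSet(_seed_rows(0, range(0, n, 8), lambda b: x_bright - 1,
                               lambda b: n / 2)), n)
        with pytest.raises(ValueError, match="chamber interior"):
            segment_chamber(vol, seeds, self.BAND, "posterior")

    def test_deterministic(self):
        vol, _ = _ring_volume()
        n = vol.shape[0]
        seeds = interpolate_seeds(
            SeedSet(_seed_rows(0, range(0, n, 8),
                               lambda b: n / 2 + 0.35 / 0.02,
                               lambda b: n / 2)), n)
        m1 = segment_chamber(vol, seeds, self.BAND, "posterior")
        m2 = segment_chamber(vol, seeds, self.BAND, "posterior")
        assert np.array_equal(m1.mask, m2.mask)


class TestMergeMasks:
    @staticmethod
    def _mask_from(arr, spacing=20.0):
        return ChamberMask(arr, "view", "posterior", np.full(3, spacing))

    def test_single_identity_mask_unchanged(self, rng):
        arr = rng.random((24, 24, 24)) > 0.6
        m = self._mask_from(arr)
        out = merge_masks([m], [RigidTransform.identity()],
                          ((24, 24, 24), np.full(3, 20.0), np.zeros(3)))
        assert np.array_equal(out.mask, arr)

    def test_half_ring_sectors_union_to_full_ring(self):
        """Two complementary half-torus masks union to the full ring volume."""
        n, sp = 72, 20.0
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        x = (ii - n / 2) * sp / 1000.0
        y = (jj - n / 2) * sp / 1000.0
        z = (kk - n / 2) * sp / 1000.0
        ring = (np.hypot(np.hypot(x, y) - 0.4, z) < 0.15)
        left = ring & (x <= 0)
        right = ring & (x >= 0)
        out = merge_masks([self._mask_from(left), self._mask_from(right)],
                          [RigidTransform.identity()] * 2,
                          ((n, n, n), np.full(3, sp), np.zeros(3)))
        assert out.voxel_count() == pytest.approx(ring.sum(), rel=0.02)

    def test_union_is_monotone_and_commutative(self, rng):
        a = self._mask_from(rng.random((16, 16, 16)) > 0.5)
        b = self._mask_from(rng.random((16, 16, 16)) > 0.5)
        grid = ((16, 16, 16), np.full(3, 20.0), np.zeros(3))
        tfs = [RigidTransform.identity()] * 2
        ab = merge_masks([a, b], tfs, grid)
        ba = merge_masks([b, a], tfs, grid)
        only_a = merge_masks([a], tfs[:1], grid)
        assert np.array_equal(ab.mask, ba.mask)
        assert not (only_a.mask & ~ab.mask).any()  # adding a view never shrinks

    def test_disjoint_masks_add_exactly(self):
        a = np.zeros((16, 16, 16), dtype=bool)
        b = np.zeros((16, 16, 16), dtype=bool)
        a[2:5, 2:5, 2:5] = True
        b[10:14, 10:14, 10:14] = True
        out = merge_masks([self._mask_from(a), self._mask_from(b)],
                          [RigidTransform.identity()] * 2,
                          ((16, 16, 16), np.full(3, 20.0), np.zeros(3)))
        assert out.voxel_count() == a.sum() + b.sum()

    def test_transform_count_mismatch_rejected(self, rng):
        m = self._mask_from(rng.random((8, 8, 8)) > 0.5)
        with pytest.raises(ValueError, match="transform"):
            merge_masks([m], [], ((8, 8, 8), np.full(3, 20.0), np.zeros(3)))
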