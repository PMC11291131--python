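"""Per-B-scan chamber segmentation and volumetric mask merging.

The acquisition workflow marks inlier/outlier guide points every
``stride`` B-scans, interpolates each tracked point's trajectory across
B-scans with a third-order polynomial, and then segments every B-scan.
The segmentation backend here is deterministic seeded region growing:
each B-scan is partitioned into connected components of the chamber
intensity band (dark aqueous, barred by bright tissue ridges), components
containing an inlier seed are kept and components containing an outlier
seed are removed.  Per-view chamber masks are mapped into the common
frame with nearest-neighbour resampling and combined by voxelwise union.

The backend is intentionally pluggable: any callable with the
``segment_chamber`` signature (volume + dense seeds -> mask) can stand in
for it, mirroring workflows that use an interactively promptable neural
segmenter for the same role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import ChamberMask, RigidTransform, VoxelVolume

__all__ = ["SeedSet", "interpolate_seeds", "segment_chamber", "merge_masks"]


@dataclass
class SeedSet:
    """Guide points for seeded segmentation.

    Each seed row is ``(track_id, bscan_index, x, z)`` in voxel
    coordinates; ``track_id`` groups the repeated picks of one physical
    point across B-scans so its trajectory can be interpolated.  Inlier
    points lie inside the chamber; outlier points mark regions that must
    be excluded.
    """

    inlier_points: np.ndarray
    outlier_points: np.ndarray = field(
        default_factory=lambda: np.empty((0, 4), dtype=float))
    stride: int = 50

    def __post_init__(self) -> None:
        self.inlier_points = np.asarray(self.inlier_points, dtype=float).reshape(-1, 4)
        self.outlier_points = np.asarray(self.outlier_points, dtype=float).reshape(-1, 4)
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.inlier_points.shape[0] < 1:
            raise ValueError("at least one inlier seed is required")
        if self.outlier_points.shape[0]:
            a = {tuple(p) for p in np.round(self.inlier_points, 9)}
            b = {tuple(p) for p in np.round(self.outlier_points, 9)}
            if a & b:
                raise ValueError("inlier and outlier seeds must be disjoint")

    def seeded_bscans(self) -> np.ndarray:
        return np.unique(self.inlier_points[:, 1].astype(int))


def _interp_tracks(points: np.ndarray, n_bscans: int) -> np.ndarray:
    """Cubic least-squares interpolation of (track_id, b, x, z) rows."""
    if points.shape[0] == 0:
        return points
    out = []
    for tid in np.unique(points[:, 0]):
        rows = points[points[:, 0] == tid]
        b = rows[:, 1]
        if np.unique(b).size < 4:
            raise ValueError(
                f"track {tid:g}: cubic interpolation needs >= 4 seeded B-scans")
        # least-squares cubic in the B-scan index, per coordinate;
        # centred/scaled for conditioning
        b0, bs = b.mean(), max(b.std(), 1.0)
        design = np.vander((b - b0) / bs, 4)
        coef_x, *_ = np.linalg.lstsq(design, rows[:, 2], rcond=None)
        coef_z, *_ = np.linalg.lstsq(design, rows[:, 3], rcond=None)
        bb = np.arange(int(np.floor(b.min())), int(np.ceil(b.max())) + 1)
        bb = bb[(bb >= 0) & (bb < n_bscans)]
        t = (bb - b0) / bs
        out.append(np.column_stack([
            np.full(bb.size, tid), bb,
            np.polyval(coef_x, t), np.polyval(coef_z, t)]))
    return np.vstack(out)


def interpolate_seeds(seeds: SeedSet, n_bscans: int) -> SeedSet:
    """Densify sparse guide points to one seed per B-scan per track.

    For each tracked point, x(b) and z(b) are fitted by least-squares
    cubic polynomials in the B-scan index b and evaluated at every
    B-scan within the track's seeded range.
    """
    dense_in = _interp_tracks(seeds.inlier_points, n_bscans)
    dense_out = _interp_tracks(seeds.outlier_points, n_bscans)
    return SeedSet(dense_in, dense_out, stride=1)


def segment_chamber(volume: VoxelVolume, dense_seeds: SeedSet,
                    intensity_band: tuple[float, float], chamber: str,
                    strict_seeds: bool = True) -> ChamberMask:
    """Segment one chamber by per-B-scan seeded region growing.

    Each B-scan (x–z image) is thresholded to the chamber intensity band
    and partitioned into 4-connected components, so supra-band boundary
    ridges cannot be crossed.  Components containing an inlier seed are
    kept; components containing an outlier seed are removed (exclusion
    wins).  The 2D masks are stacked into a 3D :class:`ChamberMask`.

    With ``strict_seeds`` (default) an inlier seed that falls on an
    out-of-band voxel raises; otherwise it is skipped with a warning,
    which lets degenerate inputs (e.g. a phantom with no cavity) yield an
    empty mask instead of failing.
    """
    lo, hi = intensity_band
    nx, n_bscans, nz = volume.shape
    mask = np.zeros(volume.shape, dtype=bool)

    def _by_bscan(points):
        table: dict[int, list[tuple[int, int]]] = {}
        for _, b, x, z in points:
            bi = int(round(b))
            xi, zi = int(round(x)), int(round(z))
            if not (0 <= bi < n_bscans and 0 <= xi < nx and 0 <= zi < nz):
                raise ValueError(f"seed ({bi}, {xi}, {zi}) lies outside the volume")
            table.setdefault(bi, []).append((xi, zi))
        return table

    inl = _by_bscan(dense_seeds.inlier_points)
    outl = _by_bscan(dense_seeds.outlier_points)

    for b, seeds_xy in inl.items():
        img = volume.intensities[:, b, :]
        band = (img >= lo) & (img <= hi)
        labels, _ = ndimage.label(band)  # 4-connectivity in-plane
        keep: set[int] = set()
        for xi, zi in seeds_xy:
            lab = labels[xi, zi]
            if lab == 0:
                if strict_seeds:
                    raise ValueError(
                        f"seed not in chamber interior: B-scan {b}, ({xi}, {zi}) "
                        "is on a boundary-intensity voxel")
                warnings.warn(f"B-scan {b}: inlier seed on boundary voxel skipped")
                continue
            keep.add(int(lab))
        for xi, zi in outl.get(b, []):
            lab = int(labels[xi, zi])
            if lab != 0:
                keep.discard(lab)
        if keep:
            mask[:, b, :] = np.isin(labels, sorted(keep))

    if not mask.any():
        warnings.warn(f"{chamber} chamber segmentation produced an empty mask")
    return ChamberMask(mask, volume.frame_id, chamber,
                       spacing=volume.spacing, origin=volume.origin)


def merge_masks(masks: list[ChamberMask], transforms: list[RigidTransform],
                out_grid: tuple[tuple[int, int, int], np.ndarray, np.ndarray],
                chunk_slices: int = 32) -> ChamberMask:
    """Union of per-view chamber masks on a common grid.

    ``out_grid`` is ``(shape, spacing_um, origin_mm)`` in the common
    frame; ``transforms[k]`` maps view k into that frame.  Each mask is
    resampled with nearest-neighbour interpolation (preserving binarity)
    and the output is the voxelwise union.
    """
    if len(masks) != len(transforms):
        raise ValueError("grid mismatch: need one transform per mask")
    shape, spacing, origin = out_grid
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("grid mismatch: output spacing must be positive")

    out = np.zeros(shape, dtype=bool)
    sp_mm = spacing / 1000.0
    ys = np.arange(shape[1]) * sp_mm[1] + origin[1]
    zs = np.arange(shape[2]) * sp_mm[2] + origin[2]
    for x0 in range(0, shape[0], chunk_slices):
        x1 = min(x0 + chunk_slices, shape[0])
        xs = np.arange(x0, x1) * sp_mm[0] + origin[0]
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        chunk = np.zeros(pts.shape[0], dtype=bool)
        for m, tf in zip(masks, transforms):
            local = tf.inverse().apply(pts)
            idx = np.rint((local - m.origin) / m.spacing_mm).astype(int)
            inside = np.all((idx >= 0) & (idx < np.asarray(m.mask.shape)), axis=1)
            if inside.any():
                sel = idx[inside]
                chunk[inside] |= m.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        out[x0:x1] = chunk.reshape(x1 - x0, shape[1], shape[2])

    chamber = masks[0].chamber if masks else "posterior"
    return ChamberMask(out, "common", chamber, spacing=spacing, origin=origin)
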