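"""Posterior-chamber boundary correction at the anterior hyaloid membrane.

The anterior hyaloid membrane — the posterior limit of the posterior
chamber — is too tenuous to image directly, so raw posterior-chamber
segmentations stop early at a spurious interface running from the lens to
the ciliary body and underestimate the chamber.  The correction
approximates the membrane by the equator of the eye: an axis-aligned
ellipsoid is fitted to the anterior lens surface (extracted from the
chamber masks), the equatorial plane is taken through the ellipsoid
center normal to the optical axis, and the posterior-chamber mask is
extended down to that plane (and truncated at it), staying outside the
lens and inside the chamber's outer wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ChamberMask, PointCloud

__all__ = [
    "EllipsoidFit",
    "Plane",
    "extract_lens_surface",
    "fit_ellipsoid",
    "equatorial_plane",
    "correct_posterior_mask",
]


@dataclass(frozen=True)
class EllipsoidFit:
    """An axis-aligned ellipsoid ((x-cx)/a)² + ((y-cy)/b)² + ((z-cz)/c)² = 1."""

    center: np.ndarray
    semi_axes: np.ndarray
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=float))
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    def contains(self, pts: np.ndarray, scale: float = 1.0) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        q = np.sum(((pts - self.center) / (scale * self.semi_axes)) ** 2, axis=-1)
        return q < 1.0


@dataclass(frozen=True)
class Plane:
    """A plane given by a point (mm) and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / nn)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.point) @ self.normal


def extract_lens_surface(ac_mask: ChamberMask, pc_mask: ChamberMask,
                         aperture_radius: float | None = None) -> PointCloud:
    """Anterior lens surface points from the chamber masks.

    The posterior boundary of the anterior chamber within the pupil
    aperture and the inner (lens-side) boundary of the posterior chamber
    are both taken to coincide with the anterior lens surface.  If
    ``aperture_radius`` is not given, it is estimated from the AC
    boundary itself: the modal boundary depth identifies the flat iris
    plane, and boundary voxels anterior to it (the lens cap bulging
    through the pupil) are kept.
    """
    if not ac_mask.mask.any() and not pc_mask.mask.any():
        raise ValueError("both chamber masks are empty")
    if ac_mask.mask.shape == pc_mask.mask.shape and np.any(
            ac_mask.mask & pc_mask.mask):
        raise ValueError("anterior and posterior chamber masks overlap")

    pts = []

    if ac_mask.mask.any():
        m = ac_mask.mask
        post_exit = m.copy()
        post_exit[:, :, :-1] &= ~m[:, :, 1:]   # posterior (+z) neighbour outside
        post_exit[:, :, -1] = m[:, :, -1]
        idx = np.argwhere(post_exit)
        coords = ac_mask.origin + idx * ac_mask.spacing_mm
        # boundary voxel centers sit half a voxel inside the chamber;
        # offset onto the interface
        coords = coords + [0.0, 0.0, 0.5 * ac_mask.spacing_mm[2]]
        if aperture_radius is not None:
            lat_center = (np.argwhere(m)[:, :2] * ac_mask.spacing_mm[:2]).mean(axis=0) \
                + ac_mask.origin[:2]
            r = np.hypot(coords[:, 0] - lat_center[0], coords[:, 1] - lat_center[1])
            sel = r < aperture_radius
        else:
            # iris plane = modal boundary depth; lens cap lies anterior to
            # it (50 µm physical margin)
            z_idx = idx[:, 2]
            modal = np.bincount(z_idx).argmax()
            sel = z_idx < modal - max(1, int(round(0.05 / ac_mask.spacing_mm[2])))
        pts.append(coords[sel])

    if pc_mask.mask.any():
        # the chamber's inner (lens-side) boundary: the innermost mask voxel
        # per meridian and depth — robust to ragged mask surfaces
        m = pc_mask.mask
        idx = np.argwhere(m)
        coords = pc_mask.origin + idx * pc_mask.spacing_mm
        lat_center = (idx * pc_mask.spacing_mm)[:, :2].mean(axis=0) + pc_mask.origin[:2]
        dx = coords[:, 0] - lat_center[0]
        dy = coords[:, 1] - lat_center[1]
        r = np.maximum(np.hypot(dx, dy), 1e-9)
        n_theta = 72
        theta = np.arctan2(dy, dx)
        tbin = ((theta + np.pi) / (2.0 * np.pi) * n_theta).astype(int) % n_theta
        key = tbin * m.shape[2] + idx[:, 2]
        order = np.lexsort((r, key))
        first = np.ones(len(order), dtype=bool)
        first[1:] = key[order[1:]] != key[order[:-1]]
        sel = order[first]
        # the innermost of several voxels per bin already sits close to the
        # surface, so no half-voxel offset is applied here
        pts.append(coords[sel])
    else:
        warnings.warn("posterior chamber mask empty: using the anterior-chamber "
                      "lens boundary alone")

    if not pts or sum(len(p) for p in pts) == 0:
        raise ValueError("no lens-surface points could be extracted")
    return PointCloud(np.vstack([p for p in pts if len(p)]),
                      frame_id=ac_mask.frame_id)


def fit_ellipsoid(points: PointCloud, trim_iterations: int = 0) -> EllipsoidFit:
    """Least-squares axis-aligned ellipsoid through a point cloud.

    Solves the quadric form ``A x² + B y² + C z² + D x + E y + F z = 1``
    by linear least squares and extracts center and semi-axes.  The fit
    is restricted to axis-aligned ellipsoids because the optical axis is
    fixed by the montage frame; this avoids the instability of a full
    9-parameter quadric on cap-only data.

    With ``trim_iterations`` > 0 the fit is repeated after discarding
    points whose residual exceeds 3 × the MAD-based robust scale — a light
    robustification against stray boundary voxels off the lens — and the
    final algebraic solution is polished by a geometric (orthogonal
    distance) least-squares step, which removes the curvature-dependent
    shrinkage the algebraic form suffers under voxel-quantization noise.
    """
    fit = _fit_ellipsoid_once(points.points)
    for _ in range(trim_iterations):
        p = points.points
        q = np.sum(((p - fit.center) / fit.semi_axes) ** 2, axis=1)
        grad = 2.0 * np.linalg.norm((p - fit.center) / fit.semi_axes**2, axis=1)
        res = np.abs(q - 1.0) / np.maximum(grad, 1e-12)
        scale = 1.4826 * np.median(res)  # MAD: robust to the outliers themselves
        keep = res <= 3.0 * max(scale, 1e-12)
        if keep.sum() < 10 or keep.all():
            break
        points = PointCloud(p[keep], points.frame_id)
        fit = _fit_ellipsoid_once(points.points)
    if trim_iterations > 0:
        fit = _refine_geometric(points.points, fit)
    return fit


def _refine_geometric(p: np.ndarray, fit: EllipsoidFit) -> EllipsoidFit:
    """Gauss–Newton polish minimizing first-order orthogonal distances."""
    from scipy.optimize import least_squares

    def residuals(theta):
        center, axes = theta[:3], np.abs(theta[3:]) + 1e-9
        u = (p - center) / axes
        q = np.sum(u**2, axis=1)
        grad = 2.0 * np.linalg.norm(u / axes, axis=1)
        return (q - 1.0) / np.maximum(grad, 1e-12)

    x0 = np.concatenate([fit.center, fit.semi_axes])
    sol = least_squares(residuals, x0, method="lm", max_nfev=60)
    center, axes = sol.x[:3], np.abs(sol.x[3:])
    res = residuals(sol.x)
    return EllipsoidFit(center=center, semi_axes=axes,
                        rms_residual=float(np.sqrt(np.mean(res**2))),
                        n_points=p.shape[0])


def _fit_ellipsoid_once(p: np.ndarray) -> EllipsoidFit:
    if p.shape[0] < 10:
        raise ValueError("ellipsoid fit requires at least 10 points")
    lateral_span = np.ptp(p[:, 0]) * np.ptp(p[:, 1])
    if lateral_span < 2.0:
        raise ValueError("ill-conditioned fit: points span < 2 mm² laterally")
    c = p - p.mean(axis=0)
    if np.linalg.svd(c, compute_uv=False)[2] <= 1e-9 * np.abs(p).max():
        raise ValueError("ill-conditioned fit: points are degenerate/co-planar")

    # homogeneous quadric A x² + B y² + C z² + D x + E y + F z + G = 0,
    # solved scale-invariantly as the smallest right singular vector
    design = np.column_stack([p**2, p, np.ones(p.shape[0])])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    coef = vt[-1]
    quad, lin, const = coef[:3], coef[3:6], coef[6]
    if np.any(quad == 0) or np.any(np.sign(quad) != np.sign(quad[0])):
        raise ValueError("ill-conditioned fit: non-ellipsoidal quadric")
    if quad[0] < 0:
        quad, lin, const = -quad, -lin, -const
    center = -lin / (2.0 * quad)
    rhs = -const + np.sum(lin**2 / (4.0 * quad))
    if rhs <= 0:
        raise ValueError("negative squared semi-axis in ellipsoid fit")
    semi_axes = np.sqrt(rhs / quad)

    # geometric-ish residual: algebraic residual scaled by the local gradient
    q = np.sum(((p - center) / semi_axes) ** 2, axis=1)
    grad = 2.0 * np.linalg.norm((p - center) / semi_axes**2, axis=1)
    res = np.abs(q - 1.0) / np.maximum(grad, 1e-12)
    return EllipsoidFit(center=center, semi_axes=semi_axes,
                        rms_residual=float(np.sqrt(np.mean(res**2))),
                        n_points=p.shape[0])


def equatorial_plane(fit: EllipsoidFit, optical_axis=(0.0, 0.0, 1.0)) -> Plane:
    """Plane through the lens center, normal to the optical axis.

    This operationalizes the equator of the eye as the anterior hyaloid
    membrane's location; a non-unit ``optical_axis`` is normalized.
    """
    return Plane(point=fit.center, normal=np.asarray(optical_axis, dtype=float))


def _meridian_wall_radius(boundary: PointCloud, axis_xy: np.ndarray,
                          n_theta: int) -> np.ndarray:
    """Per-meridian outer-wall radius from the boundary cloud.

    The chamber wall below the ciliary body runs essentially parallel to
    the optical axis (pars plana), so each meridian's wall is taken at
    the maximal boundary radius observed there; meridians without
    boundary points fall back to the global maximum.
    """
    p = boundary.points
    r = np.hypot(p[:, 0] - axis_xy[0], p[:, 1] - axis_xy[1])
    theta = np.arctan2(p[:, 1] - axis_xy[1], p[:, 0] - axis_xy[0])
    tbin = ((theta + np.pi) / (2.0 * np.pi) * n_theta).astype(int) % n_theta
    r_wall = np.full(n_theta, -np.inf)
    np.maximum.at(r_wall, tbin, r)
    r_wall[~np.isfinite(r_wall)] = r.max()
    # circular median filter: a stray boundary voxel should not widen the
    # wall of its whole meridian
    pad = 2
    ext = np.concatenate([r_wall[-pad:], r_wall, r_wall[:pad]])
    return np.median(np.lib.stride_tricks.sliding_window_view(ext, 2 * pad + 1),
                     axis=1)


def correct_posterior_mask(pc_mask: ChamberMask, plane: Plane,
                           lens_fit: EllipsoidFit, outer_boundary: PointCloud,
                           n_theta: int = 180) -> ChamberMask:
    """Update the posterior-chamber mask at the estimated hyaloid plane.

    The corrected mask is ``(original ∪ fill) ∩ {anterior side of the
    plane}``.  The fill region comprises voxels anterior to the plane,
    outside the fitted lens ellipsoid, radially inside the chamber's
    outer wall (an axis-centred sphere fitted to ``outer_boundary``), and
    within the original mask's per-meridian angular support, extending
    each meridian from the original mask's anterior limit down to the
    plane.  The correction therefore only ever *adds* volume when the
    original mask lies entirely anterior to the plane.
    """
    m = pc_mask.mask
    if not m.any():
        raise ValueError("posterior chamber mask is empty")
    idx = np.argwhere(m)
    coords = pc_mask.origin + idx * pc_mask.spacing_mm

    # plane must intersect the mask's grid bounding box
    lo = pc_mask.origin - pc_mask.spacing_mm
    hi = pc_mask.origin + np.asarray(m.shape) * pc_mask.spacing_mm
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    s = plane.signed_distance(corners)
    if np.all(s > 0) or np.all(s < 0):
        raise ValueError("plane lies entirely outside the mask bounding box")

    axis_xy = lens_fit.center[:2]
    theta = np.arctan2(coords[:, 1] - axis_xy[1], coords[:, 0] - axis_xy[0])
    tbin = ((theta + np.pi) / (2.0 * np.pi) * n_theta).astype(int) % n_theta
    support = np.zeros(n_theta, dtype=bool)
    support[tbin] = True
    # anterior (minimum signed-distance... here: minimum z along the axis)
    sd = plane.signed_distance(coords)
    z_top = np.full(n_theta, np.inf)
    np.minimum.at(z_top, tbin, sd)

    # full-grid fill evaluation
    shape = m.shape
    sp = pc_mask.spacing_mm
    gi, gj, gk = np.meshgrid(*[np.arange(s_) for s_ in shape], indexing="ij")
    pts = pc_mask.origin + np.stack([gi, gj, gk], axis=-1) * sp
    flat = pts.reshape(-1, 3)
    sd_all = plane.signed_distance(flat)
    anterior = sd_all <= 0.0

    th_all = np.arctan2(flat[:, 1] - axis_xy[1], flat[:, 0] - axis_xy[0])
    tb_all = ((th_all + np.pi) / (2.0 * np.pi) * n_theta).astype(int) % n_theta
    r_all = np.hypot(flat[:, 0] - axis_xy[0], flat[:, 1] - axis_xy[1])
    r_wall = _meridian_wall_radius(outer_boundary, axis_xy, n_theta)

    fill = (anterior
            & support[tb_all]
            & (sd_all >= z_top[tb_all])
            & (r_all <= r_wall[tb_all])
            & ~lens_fit.contains(flat))
    corrected = (m.reshape(-1) | fill) & anterior & ~lens_fit.contains(flat)
    return pc_mask.like(corrected.reshape(shape))
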