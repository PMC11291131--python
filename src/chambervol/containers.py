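"""Shared data containers for ocular-chamber volumetry.

Conventions used throughout the package
---------------------------------------
* Physical coordinates are in **mm**; voxel spacings are stored in
  **µm/voxel** (the native scale of anterior-segment OCT).
* Voxel indices are 0-based and refer to voxel *centers*: the physical
  position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
* Volume axis order is ``(x, y, z)`` where ``z`` is the axial (beam/depth)
  direction and ``y`` indexes B-scans (a B-scan is an x–z image).
* The optical axis of the eye coincides with ``+z`` of the common montage
  frame, pointing posteriorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelVolume",
    "PointCloud",
    "RigidTransform",
    "ChamberMask",
]

_UM_PER_MM = 1000.0


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with physical spacing and pose metadata.

    Parameters
    ----------
    intensities
        Non-negative scalar grid, axis order ``(x, y, z)``.
    spacing
        Per-axis voxel spacing in µm/voxel.
    frame_id
        Name of the coordinate frame the grid lives in (e.g. ``"view_3"``
        or ``"common"``).
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``'s center.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    frame_id: str = "common"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if any(s < 2 for s in self.intensities.shape):
            raise ValueError("grid dimensions must be >= 2 per axis")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive components (µm)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def spacing_mm(self) -> np.ndarray:
        return self.spacing / _UM_PER_MM

    def voxel_volume_ul(self) -> float:
        """Physical volume of one voxel in µL (= mm³)."""
        return float(np.prod(self.spacing_mm))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices, shape (..., 3), to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing_mm

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates, shape (..., 3), to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) / self.spacing_mm

    def grid_coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        )


@dataclass
class PointCloud:
    """A set of N points (mm) tagged with the frame they are expressed in."""

    points: np.ndarray
    frame_id: str = "common"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an N x 3 array")
        if self.points.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


_ORTHO_TOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rigid transform ``p -> R p + t`` (rotation + translation, mm).

    The rotation must be orthonormal with determinant +1 to within 1e-8;
    composition and inversion stay closed under these invariants.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation is not orthonormal (max error {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation must have determinant +1 (proper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        rot = _reorthonormalize(self.rotation @ other.rotation)
        return RigidTransform(rot, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _reorthonormalize(rot: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) to stop drift in long compositions."""
    u, _, vt = np.linalg.svd(rot)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class ChamberMask:
    """A binary 3D chamber mask on the same grid as its reference volume."""

    mask: np.ndarray
    frame_id: str
    chamber: str
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if self.chamber not in ("anterior", "posterior", "cavity"):
            raise ValueError("chamber must be 'anterior', 'posterior' or 'cavity'")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def spacing_mm(self) -> np.ndarray:
        return self.spacing / _UM_PER_MM

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def voxel_coords_mm(self) -> np.ndarray:
        """Physical coordinates (mm) of all set voxels, shape (N, 3)."""
        idx = np.argwhere(self.mask)
        return self.origin + idx * self.spacing_mm

    def like(self, mask: np.ndarray, chamber: str | None = None) -> "ChamberMask":
        return ChamberMask(
            mask, self.frame_id, chamber or self.chamber, self.spacing, self.origin
        )
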