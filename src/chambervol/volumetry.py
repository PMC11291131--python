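"""Voxel volumetry and morphometric summaries of chamber masks.

Volumes are voxel counts times the physical voxel volume; eye size is
proxied by the distance between the apexes of the iridocorneal angle on
opposite sides of the eye; histology-style half-profiles are turned into
volumes as solids of revolution; and per-eye tables are summarised as
mean ± SD with t-based 95 % confidence intervals and Welch comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Polygon

from .containers import ChamberMask

__all__ = [
    "VolumeReport",
    "mask_volume",
    "angle_apex_separation",
    "volume_of_revolution",
    "summarize",
    "plot_volume_summary",
]


def mask_volume(mask: ChamberMask, spacing=None) -> float:
    """Volume of a binary mask in µL (voxel count × voxel volume).

    ``spacing`` (µm/voxel) defaults to the mask's own spacing.
    """
    sp = np.asarray(spacing, dtype=float) if spacing is not None else mask.spacing
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    voxel_ul = float(np.prod(sp / 1000.0))  # mm³ == µL
    return mask.voxel_count() * voxel_ul


def angle_apex_separation(ac_mask: ChamberMask, n_theta: int = 72) -> float:
    """Mean apex-to-apex distance (mm) across the iridocorneal angle.

    The apex of the angle at each meridian is the most peripheral
    anterior-chamber voxel (maximum cylindrical radius about the optical
    axis); the separation is averaged over diametrically opposite
    meridian pairs.  Raises if the mask periphery is open (some meridian
    contains no mask voxels).
    """
    if not ac_mask.mask.any():
        raise ValueError("anterior chamber mask is empty")
    coords = ac_mask.voxel_coords_mm()
    center = coords[:, :2].mean(axis=0)
    dx, dy = coords[:, 0] - center[0], coords[:, 1] - center[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    tbin = ((theta + np.pi) / (2.0 * np.pi) * n_theta).astype(int) % n_theta
    if np.unique(tbin).size < n_theta:
        raise ValueError("open periphery: some meridians contain no mask voxels")
    apex = np.zeros((n_theta, 3))
    for b in range(n_theta):
        sel = tbin == b
        apex[b] = coords[sel][np.argmax(r[sel])]
    half = n_theta // 2
    d = np.linalg.norm(apex[:half] - apex[half:], axis=1)
    return float(d.mean())


def volume_of_revolution(half_profile: np.ndarray, axis: str = "z") -> float:
    """Volume (µL) of the solid swept by revolving a half-profile.

    ``half_profile`` is an ordered polyline of (r, axial) vertices in mm
    lying on one side of the revolution axis (r >= 0); an open polyline
    is closed along the axis.  The swept volume is the cylindrical-shell
    integral ``2π ∬ r dr dz``, evaluated exactly for the polygonal
    profile via Pappus's centroid theorem (rotating the half-profile
    through 180° on both sides generates the full solid).
    """
    prof = np.asarray(half_profile, dtype=float)
    if prof.ndim != 2 or prof.shape[1] != 2 or prof.shape[0] < 3:
        raise ValueError("half_profile must be an ordered (N>=3) x 2 polyline")
    if axis not in ("z", "y", "x"):
        raise ValueError("axis must be a coordinate-axis label")
    if np.any(prof[:, 0] < -1e-12):
        raise ValueError("profile crosses the revolution axis (negative radius)")
    ring = prof if np.allclose(prof[0], prof[-1]) else np.vstack([prof, prof[:1]])
    if not LineString(prof).is_simple:
        raise ValueError("profile polyline is self-intersecting")
    poly = Polygon(ring)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("profile does not enclose a region")
    return float(2.0 * np.pi * poly.area * poly.centroid.x)


@dataclass
class VolumeReport:
    """Per-eye chamber volumes with cohort summary statistics."""

    per_eye: pd.DataFrame
    summary: pd.DataFrame
    comparison: dict | None = None

    @property
    def ac_volume(self) -> float:
        return float(self.per_eye["ac_volume"].mean())

    @property
    def pc_volume(self) -> float:
        return float(self.per_eye["pc_volume"].mean())

    @property
    def ac_fraction(self) -> float:
        return float(self.per_eye["ac_fraction"].mean())


def _agg(values: np.ndarray) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1) if n > 1 else np.nan
    return {"n": n, "mean": mean, "sd": sd,
            "ci95_lo": mean - tcrit * se, "ci95_hi": mean + tcrit * se}


def summarize(per_eye_volumes: pd.DataFrame) -> VolumeReport:
    """Cohort summary of per-eye chamber volumes.

    ``per_eye_volumes`` needs columns ``ac_volume`` and ``pc_volume``
    (µL), optionally ``angle_apex_separation`` (mm) and ``group``.
    Derived per-eye quantities (total, AC:PC ratio, AC fraction) are
    added, then aggregated as mean, SD (n−1 denominator) and t-based
    95 % CI.  With exactly two groups, a Welch (unequal-variance)
    two-sample comparison of AC volume is reported.
    """
    df = per_eye_volumes.copy()
    if len(df) < 2:
        raise ValueError("summary requires n >= 2 eyes")
    df["total_volume"] = df["ac_volume"] + df["pc_volume"]
    df["ac_pc_ratio"] = df["ac_volume"] / df["pc_volume"]
    df["ac_fraction"] = df["ac_volume"] / df["total_volume"]

    metrics = ["ac_volume", "pc_volume", "total_volume", "ac_pc_ratio",
               "ac_fraction"]
    if "angle_apex_separation" in df.columns:
        metrics.append("angle_apex_separation")
    summary = pd.DataFrame({m: _agg(df[m].to_numpy()) for m in metrics}).T

    comparison = None
    if "group" in df.columns and df["group"].nunique() == 2:
        g1, g2 = sorted(df["group"].unique())
        a = df.loc[df["group"] == g1, "ac_volume"].to_numpy()
        b = df.loc[df["group"] == g2, "ac_volume"].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        comparison = {"groups": (g1, g2), "metric": "ac_volume",
                      "t": float(t), "p": float(p), "test": "welch"}
    return VolumeReport(per_eye=df, summary=summary, comparison=comparison)


def plot_volume_summary(report: VolumeReport, path,
                        metrics=("ac_volume", "pc_volume")) -> None:
    """Bar chart of cohort volumes with 95 % CI error bars (SVG/PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = [report.summary.loc[m, "mean"] for m in metrics]
    los = [report.summary.loc[m, "mean"] - report.summary.loc[m, "ci95_lo"]
           for m in metrics]
    his = [report.summary.loc[m, "ci95_hi"] - report.summary.loc[m, "mean"]
           for m in metrics]
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    x = np.arange(len(metrics))
    ax.bar(x, means, width=0.6, color="#88aacc", edgecolor="black")
    ax.errorbar(x, means, yerr=[los, his], fmt="none", ecolor="black",
                capsize=4)
    ax.set_xticks(x)
    ax.set_xticklabels([m.replace("_volume", "").upper() for m in metrics])
    ax.set_ylabel("volume (µL)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
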