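"""File formats and provenance for pipeline artifacts.

Volumes and masks are written as multi-page TIFF or NIfTI-1 (chosen by
extension); spacing/origin/frame metadata ride in the NIfTI affine or in
a JSON sidecar for TIFF.  Transforms are 4×4 homogeneous matrices in
JSON, landmarks and seeds are CSV tables, and every artifact gets a
provenance sidecar recording the stage, parameters, seed and SHA-256
hashes of its inputs so runs can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .containers import ChamberMask, RigidTransform, VoxelVolume

__all__ = [
    "write_volume", "read_volume", "write_mask", "read_mask",
    "write_transforms", "read_transforms",
    "write_landmarks", "read_landmarks",
    "write_seeds", "read_seeds",
    "write_json", "file_sha256", "ArtifactWriter",
]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path, payload) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# -- volumes ----------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume as .tif/.tiff (pages = axial slices) or .nii/.nii.gz."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        affine = np.diag([*volume.spacing_mm, 1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(np.asarray(volume.intensities), affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
    elif suffix.endswith((".tif", ".tiff")):
        # pages along z so each page is a lateral section
        tifffile.imwrite(path, np.moveaxis(volume.intensities, 2, 0))
        write_json(_sidecar(path), {
            "spacing_um": volume.spacing, "origin_mm": volume.origin,
            "frame_id": volume.frame_id})
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        spacing_mm = np.abs(np.diag(affine)[:3])
        return VoxelVolume(np.asarray(img.dataobj), spacing_mm * 1000.0,
                           frame_id=path.stem.split(".")[0],
                           origin=affine[:3, 3])
    if suffix.endswith((".tif", ".tiff")):
        data = np.moveaxis(tifffile.imread(path), 0, 2)
        meta_path = _sidecar(path)
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            return VoxelVolume(data, np.asarray(meta["spacing_um"]),
                               frame_id=meta.get("frame_id", path.stem),
                               origin=np.asarray(meta["origin_mm"]))
        return VoxelVolume(data, np.ones(3), frame_id=path.stem)
    raise ValueError(f"unsupported volume format: {path.name}")


def write_mask(mask: ChamberMask, path) -> Path:
    vol = VoxelVolume(mask.mask.astype(np.uint8), mask.spacing,
                      mask.frame_id, mask.origin)
    path = write_volume(vol, path)
    meta = _sidecar(path)
    if meta.exists():
        payload = json.loads(meta.read_text())
        payload["chamber"] = mask.chamber
        write_json(meta, payload)
    return path


def read_mask(path, chamber: str) -> ChamberMask:
    vol = read_volume(path)
    return ChamberMask(vol.intensities > 0, vol.frame_id, chamber,
                       vol.spacing, vol.origin)


# -- transforms, landmarks, seeds ------------------------------------------


def write_transforms(transforms: list[RigidTransform], path) -> None:
    write_json(path, {"transforms": [t.matrix() for t in transforms]})


def read_transforms(path) -> list[RigidTransform]:
    payload = json.loads(Path(path).read_text())
    return [RigidTransform.from_matrix(np.asarray(m))
            for m in payload["transforms"]]


def write_landmarks(landmark_sets: list[dict], path) -> None:
    """Landmark CSV: one row per point per frame it is expressed in."""
    rows = []
    for pair in landmark_sets:
        k0, k1 = pair["pair"]
        for pid, (d, s) in enumerate(zip(pair["dst"], pair["src"])):
            rows.append((k0, k1, pid, k0, *d))
            rows.append((k0, k1, pid, k1, *s))
    pd.DataFrame(rows, columns=["pair_a", "pair_b", "point_id", "view_id",
                                "x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def read_landmarks(path) -> list[dict]:
    df = pd.read_csv(path)
    out = []
    for (a, b), grp in df.groupby(["pair_a", "pair_b"], sort=True):
        dst = grp[grp.view_id == a].sort_values("point_id")
        src = grp[grp.view_id == b].sort_values("point_id")
        out.append({"pair": (int(a), int(b)),
                    "dst": dst[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                    "src": src[["x_mm", "y_mm", "z_mm"]].to_numpy()})
    return out


def write_seeds(seeds, chamber: str, path, view_id: int = 0) -> None:
    from .segmentation import SeedSet  # noqa: F401 (type only)
    rows = []
    for role, pts in (("in", seeds.inlier_points), ("out", seeds.outlier_points)):
        for tid, b, x, z in pts:
            rows.append((chamber, view_id, int(tid), int(b), x, z, role))
    pd.DataFrame(rows, columns=["chamber", "view_id", "track_id", "bscan",
                                "x", "z", "role"]).to_csv(path, index=False)


def read_seeds(path, chamber: str | None = None, view_id: int | None = None):
    from .segmentation import SeedSet
    df = pd.read_csv(path)
    if chamber is not None:
        df = df[df.chamber == chamber]
    if view_id is not None:
        df = df[df.view_id == view_id]
    def rows(role):
        sel = df[df.role == role]
        return sel[["track_id", "bscan", "x", "z"]].to_numpy(dtype=float)
    inl = rows("in")
    if not len(inl):
        raise ValueError(f"no inlier seeds in {path}")
    return SeedSet(inl, rows("out"))


# -- provenance-aware artifact writing --------------------------------------


class ArtifactWriter:
    """Writes pipeline artifacts plus provenance sidecars into one run dir."""

    def __init__(self, config) -> None:
        self.config = config
        self.dir = Path(config.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self._ext = ".nii.gz" if config.volume_format == "nifti" else ".tif"
        self._written: list[Path] = []

    def _provenance(self, stage: str, path: Path, extra: dict | None = None):
        cfg = dataclasses.asdict(self.config)
        cfg.pop("out_dir", None)  # a location, not a scientific parameter
        payload = {"stage": stage, "seed": self.config.seed, "parameters": cfg,
                   "inputs": {p.name: file_sha256(p) for p in self._written[-4:]}}
        if extra:
            payload.update(extra)
        write_json(path.with_name(path.name + ".provenance.json"), payload)

    def _track(self, path: Path, stage: str, extra=None) -> Path:
        self._provenance(stage, path, extra)
        self._written.append(path)
        return path

    def write_volume(self, stage: str, volume: VoxelVolume, name: str) -> Path:
        path = write_volume(volume, self.dir / f"{name}{self._ext}")
        return self._track(path, stage)

    def write_mask(self, stage: str, mask: ChamberMask, name: str) -> Path:
        path = write_mask(mask, self.dir / f"{name}{self._ext}")
        return self._track(path, stage)

    def write_acquisition(self, stage: str, acq, model) -> None:
        for k, v in enumerate(acq.views):
            self.write_volume(stage, v, f"view_{k:02d}")
        write_transforms(acq.true_transforms, self.dir / "true_transforms.json")
        self._track(self.dir / "true_transforms.json", stage)
        write_landmarks(acq.landmark_sets, self.dir / "landmarks.csv")
        self._track(self.dir / "landmarks.csv", stage)
        truth = {
            "ac_volume_true_ul": model.ac_volume_true,
            "pc_volume_true_ul": model.pc_volume_true,
            "angle_apex_separation_true_mm": model.angle_apex_separation_true,
        }
        write_json(self.dir / "ground_truth.json", truth)
        self._track(self.dir / "ground_truth.json", stage)

    def write_montage(self, stage, montage, transforms, diagnostics) -> None:
        self.write_volume(stage, montage, "montage")
        write_transforms(transforms, self.dir / "transforms.json")
        self._track(self.dir / "transforms.json", stage)
        write_json(self.dir / "fusion.json", diagnostics)
        self._track(self.dir / "fusion.json", stage)

    def write_correction(self, stage, lens_fit, plane, pc_mask) -> None:
        write_json(self.dir / "hyaloid_fit.json", {
            "lens_center_mm": lens_fit.center,
            "lens_semi_axes_mm": lens_fit.semi_axes,
            "rms_residual_mm": lens_fit.rms_residual,
            "n_points": lens_fit.n_points,
            "plane_point_mm": plane.point,
            "plane_normal": plane.normal,
        })
        self._track(self.dir / "hyaloid_fit.json", stage)
        self.write_mask(stage, pc_mask, "pc_mask_corrected")

    def write_report(self, stage, result: dict) -> None:
        write_json(self.dir / "report.json", result)
        self._track(self.dir / "report.json", stage)

    def mark_failed(self, exc: Exception) -> None:
        (self.dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
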