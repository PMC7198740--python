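"""Volume data model and NIfTI / manifest I/O.

All modules exchange 3-D volumes through :class:`VolumeImage`, a thin
container holding the scalar grid plus its world-space metadata (spacing,
origin, direction) in the RAS convention: +x right, +y anterior, +z
superior.  The posterior-to-anterior axis used by the gradient metrics is
therefore world +y, and inferior-to-superior is +z.

Files are NIfTI-1 (.nii / .nii.gz) read and written with nibabel; images
stored in any orientation are reordered to RAS on load so that world
coordinates are preserved.  Cohorts are described by a CSV manifest with
one row per case.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeImage",
    "CaseRecord",
    "VolumeReadError",
    "DimensionError",
    "GridMismatchError",
    "ManifestError",
    "read_volume",
    "write_volume",
    "load_cohort",
    "write_case",
    "write_manifest",
]

MODALITIES = ("CT", "perfusion", "ventilation", "label")
AC_FLAGS = ("AC", "NoAC", "NA")


class VolumeReadError(RuntimeError):
    """Raised when a file cannot be parsed as a NIfTI volume."""


class DimensionError(VolumeReadError):
    """Raised when an image is not three-dimensional."""


class GridMismatchError(ValueError):
    """Raised when two volumes expected on the same grid differ in shape,
    spacing, origin or direction."""


class ManifestError(ValueError):
    """Raised for malformed cohort manifests (duplicate ids, missing files)."""


@dataclass
class VolumeImage:
    """A 3-D scalar field with world-space metadata (RAS).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values indexed (i, j, k); HU for CT, counts for SPECT,
        integer codes for label volumes.
    spacing : tuple of 3 floats
        Voxel edge length in mm per axis; strictly positive.
    origin : tuple of 3 floats
        World coordinate (mm) of voxel (0, 0, 0).
    direction : (3, 3) ndarray
        Orthonormal voxel-axis direction matrix (columns are the world
        directions of the i/j/k axes).
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: str = "CT"
    ac_flag: str = "NA"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise DimensionError(
                f"expected a non-empty 3-D grid, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.ac_flag not in AC_FLAGS:
            raise ValueError(f"unknown ac_flag {self.ac_flag!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_coordinates(self) -> tuple:
        """World coordinate arrays (x, y, z), each of grid shape."""
        grids = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
        idx = np.stack(grids, axis=-1)
        w = self.voxel_to_world(idx)
        return w[..., 0], w[..., 1], w[..., 2]

    def same_grid(self, other: "VolumeImage", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_values(self, values: np.ndarray, modality: Optional[str] = None,
                    ac_flag: Optional[str] = None) -> "VolumeImage":
        """Copy of this volume's geometry carrying new voxel values."""
        return replace(
            self,
            values=np.asarray(values),
            modality=self.modality if modality is None else modality,
            ac_flag=self.ac_flag if ac_flag is None else ac_flag,
        )


def require_same_grid(a: VolumeImage, b: VolumeImage, what: str = "volumes") -> None:
    if not a.same_grid(b):
        raise GridMismatchError(f"{what} are not on the same grid")


@dataclass
class CaseRecord:
    """One subject: CT, the four SPECT reconstructions and optional labels.

    ``lung_truth`` codes 0 background / 1 right lung / 2 left lung;
    ``lobe_truth`` codes the five lobes (see :mod:`vqmaps.phantom`).
    ``truth_params`` carries the phantom's generating parameters when the
    case is synthetic (per-subject gradient strengths, warp, expected
    count rates) and is absent for real data.
    """

    case_id: str
    ct: VolumeImage
    perf_ac: VolumeImage
    perf_noac: VolumeImage
    vent_ac: VolumeImage
    vent_noac: VolumeImage
    lung_truth: Optional[VolumeImage] = None
    lobe_truth: Optional[VolumeImage] = None
    truth_params: Optional[dict] = None

    def volumes(self) -> dict:
        out = {
            "ct": self.ct,
            "perf_ac": self.perf_ac,
            "perf_noac": self.perf_noac,
            "vent_ac": self.vent_ac,
            "vent_noac": self.vent_noac,
        }
        if self.lung_truth is not None:
            out["lung"] = self.lung_truth
        if self.lobe_truth is not None:
            out["lobe"] = self.lobe_truth
        return out

    def spect(self, modality: str, ac_flag: str) -> VolumeImage:
        key = {"perfusion": "perf", "ventilation": "vent"}[modality]
        return getattr(self, f"{key}_{'ac' if ac_flag == 'AC' else 'noac'}")

    def __post_init__(self):
        for name, vol in self.volumes().items():
            if name != "ct" and not vol.same_grid(self.ct):
                raise GridMismatchError(
                    f"case {self.case_id}: {name} grid differs from CT"
                )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, modality: str = "CT", ac_flag: str = "NA") -> VolumeImage:
    """Load a NIfTI volume, reoriented to the internal RAS convention.

    Raises ``FileNotFoundError`` for a missing file, :class:`DimensionError`
    for a non-3-D image and :class:`VolumeReadError` for unreadable data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise VolumeReadError(f"cannot read {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionError(f"{path}: expected 3-D image, got {img.ndim}-D")
    img = nib.as_closest_canonical(img)  # reorder axes -> RAS, world preserved
    aff = img.affine
    rs = aff[:3, :3]
    spacing = np.linalg.norm(rs, axis=0)
    direction = rs / spacing
    values = np.asanyarray(img.dataobj)
    return VolumeImage(
        values=values,
        spacing=tuple(spacing),
        origin=tuple(aff[:3, 3]),
        direction=direction,
        modality=modality,
        ac_flag=ac_flag,
    )


def write_volume(vol: VolumeImage, path) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1 with its RAS affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.values), vol.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort manifests

_MANIFEST_COLS = ["case_id", "ct", "perf_ac", "perf_noac", "vent_ac", "vent_noac"]
_OPTIONAL_COLS = ["lung", "lobe"]


def write_case(case: CaseRecord, out_dir, compress: bool = True) -> dict:
    """Write one case's volumes to ``out_dir``; returns the manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    row = {"case_id": case.case_id}
    for name, vol in case.volumes().items():
        p = out_dir / f"{case.case_id}_{name}{ext}"
        write_volume(vol, p)
        row["ct" if name == "ct" else name] = str(p)
    return row


def write_manifest(rows: list, path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cohort(manifest_path) -> list:
    """Load a cohort manifest CSV into a list of :class:`CaseRecord`.

    Checks case-id uniqueness, file existence and per-case grid
    compatibility, raising :class:`ManifestError` / :class:`GridMismatchError`.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns {missing}")
    dup = df["case_id"][df["case_id"].duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate case_id(s): {sorted(set(dup))}")
    cases = []
    for _, row in df.iterrows():
        cid = str(row["case_id"])
        paths = {}
        for col in _MANIFEST_COLS[1:] + _OPTIONAL_COLS:
            if col in df.columns and isinstance(row.get(col), str) and row[col]:
                p = Path(row[col])
                if not p.is_absolute():
                    p = manifest_path.parent / p
                if not p.exists():
                    raise ManifestError(f"case {cid}: file not found: {p}")
                paths[col] = p
        kw = dict(
            ct=read_volume(paths["ct"], "CT"),
            perf_ac=read_volume(paths["perf_ac"], "perfusion", "AC"),
            perf_noac=read_volume(paths["perf_noac"], "perfusion", "NoAC"),
            vent_ac=read_volume(paths["vent_ac"], "ventilation", "AC"),
            vent_noac=read_volume(paths["vent_noac"], "ventilation", "NoAC"),
        )
        if "lung" in paths:
            kw["lung_truth"] = read_volume(paths["lung"], "label")
        if "lobe" in paths:
            kw["lobe_truth"] = read_volume(paths["lobe"], "label")
        cases.append(CaseRecord(case_id=cid, **kw))
    return cases
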