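"""Volumetric data model and NIfTI/JSON plan I/O.

Axis convention used throughout the package: arrays are indexed
``(slice, row, column)`` where *slice* runs craniocaudally (index 0 is the
most caudal slice), *row* runs anterior -> posterior and *column* runs the
patient's right -> left.  Spacing and origin are given in millimetres in the
same axis order.

Plans are stored on disk as one NIfTI file per volume plus a JSON manifest::

    {"id": ..., "image": ..., "dose": ..., "prescription_gy": ...,
     "n_fractions": ..., "masks": {"PTV": ..., "rectum": ..., ...}}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: Canonical region-of-interest names; every PlanSample carries all six.
ROI_NAMES = ("PTV", "rectum", "bladder", "femoral_head_L", "femoral_head_R", "body")

#: Organs at risk (structures with dose constraints, i.e. everything but PTV/body).
OAR_NAMES = ("rectum", "bladder", "femoral_head_L", "femoral_head_R")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (n_slices, n_rows, n_cols)
        Scalar voxel values (CT-like intensities, arbitrary units).
    spacing : tuple of float
        Per-axis voxel size in mm, ordered (slice, row, column).
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected 3D volume, got {v.ndim}D array")
        if v.size == 0:
            raise ValueError("volume grid is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class StructureMask:
    """A binary mask aligned to a reference grid.

    ``values`` contains only 0/1; ``roi_name`` is one of :data:`ROI_NAMES`.
    """

    roi_name: str
    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.roi_name not in ROI_NAMES:
            raise ValueError(f"unknown ROI {self.roi_name!r}; expected one of {ROI_NAMES}")
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected 3D mask, got {v.ndim}D array")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        object.__setattr__(self, "values", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass(frozen=True)
class DoseGrid:
    """A 3D absolute dose distribution in Gy plus its prescription context."""

    values: np.ndarray
    prescription: float
    n_fractions: int
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"expected 3D dose grid, got {v.ndim}D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(v < 0):
            raise ValueError("dose grid contains negative doses")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "prescription", float(self.prescription))
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def fraction_dose(self) -> float:
        """Nominal dose per fraction at prescription, in Gy."""
        return self.prescription / self.n_fractions

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return replace(self, values=values)


@dataclass(frozen=True)
class PlanSample:
    """One patient-equivalent: image, the six structure masks and a dose."""

    id: str
    image: ImageVolume
    masks: Mapping[str, StructureMask]
    dose: DoseGrid

    def __post_init__(self) -> None:
        missing = [r for r in ROI_NAMES if r not in self.masks]
        if missing:
            raise ValueError(f"plan sample {self.id!r} missing ROI(s): {', '.join(missing)}")
        shape = self.image.shape
        if self.dose.shape != shape:
            raise ValueError(
                f"grid mismatch: dose {self.dose.shape} vs image {shape} in sample {self.id!r}"
            )
        for roi, m in self.masks.items():
            if m.shape != shape:
                raise ValueError(
                    f"grid mismatch: mask {roi!r} {m.shape} vs image {shape} in sample {self.id!r}"
                )
        for roi in ROI_NAMES:
            if self.masks[roi].voxel_count == 0:
                raise ValueError(f"ROI {roi!r} is empty in sample {self.id!r}")
        object.__setattr__(self, "masks", dict(self.masks))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape

    def mask(self, roi: str) -> StructureMask:
        return self.masks[roi]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    # Our (slice,row,col) array order maps to NIfTI's fastest-varying-first
    # convention through nibabel's row-major handling: axis k of the array
    # corresponds to affine column k.
    aff = np.eye(4)
    for k in range(3):
        aff[k, k] = spacing[k]
        aff[k, 3] = origin[k]
    return aff


def write_volume(vol: ImageVolume | DoseGrid | StructureMask, path: str | Path) -> Path:
    """Write a volume as NIfTI; masks as uint8, images/doses as float32/float64.

    Dose grids are written in float64 so that storage is lossless at the
    sub-1e-5 Gy level; prescription metadata lives in the JSON manifest, not
    the NIfTI header.
    """
    path = Path(path)
    if isinstance(vol, StructureMask):
        data = vol.values.astype(np.uint8)
    elif isinstance(vol, DoseGrid):
        data = vol.values.astype(np.float64)
    else:
        data = np.asarray(vol.values, dtype=np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume`.

    Spacing is taken from the header zooms, origin from the affine
    translation.  Non-3D images and non-finite voxels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return ImageVolume(values=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def read_mask(path: str | Path, roi_name: str) -> StructureMask:
    vol = read_volume(path)
    return StructureMask(roi_name=roi_name, values=vol.values, spacing=vol.spacing, origin=vol.origin)


def read_dose(path: str | Path, prescription: float, n_fractions: int) -> DoseGrid:
    vol = read_volume(path)
    return DoseGrid(
        values=vol.values,
        prescription=prescription,
        n_fractions=n_fractions,
        spacing=vol.spacing,
        origin=vol.origin,
    )


# ---------------------------------------------------------------------------
# Plan manifests
# ---------------------------------------------------------------------------

def write_plan_sample(sample: PlanSample, out_dir: str | Path) -> Path:
    """Write a PlanSample's volumes and manifest under ``out_dir``.

    Returns the manifest path.  File names are relative inside the manifest
    so the directory can be relocated wholesale.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {"image": f"{sample.id}_image.nii.gz", "dose": f"{sample.id}_dose.nii.gz"}
    write_volume(sample.image, out_dir / names["image"])
    write_volume(sample.dose, out_dir / names["dose"])
    mask_entries = {}
    for roi in ROI_NAMES:
        fn = f"{sample.id}_mask_{roi}.nii.gz"
        write_volume(sample.masks[roi], out_dir / fn)
        mask_entries[roi] = fn
    manifest = {
        "id": sample.id,
        "image": names["image"],
        "dose": names["dose"],
        "prescription_gy": sample.dose.prescription,
        "n_fractions": sample.dose.n_fractions,
        "masks": mask_entries,
    }
    mpath = out_dir / f"{sample.id}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_plan_sample(manifest_path: str | Path) -> PlanSample:
    """Load and validate a PlanSample from a JSON manifest.

    All member grids must share one shape; the six canonical ROIs must all be
    present and non-empty.  Violations raise ``ValueError`` naming the
    offending member.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    base = manifest_path.parent
    for key in ("id", "image", "dose", "prescription_gy", "n_fractions", "masks"):
        if key not in man:
            raise ValueError(f"manifest {manifest_path} missing key {key!r}")
    missing = [r for r in ROI_NAMES if r not in man["masks"]]
    if missing:
        raise ValueError(f"manifest {man['id']!r} missing ROI(s): {', '.join(missing)}")
    image = read_volume(base / man["image"])
    dose = read_dose(base / man["dose"], man["prescription_gy"], man["n_fractions"])
    masks = {roi: read_mask(base / p, roi) for roi, p in man["masks"].items() if roi in ROI_NAMES}
    return PlanSample(id=str(man["id"]), image=image, masks=masks, dose=dose)


def load_cohort(manifest_paths: list[str | Path]) -> list[PlanSample]:
    return [load_plan_sample(p) for p in manifest_paths]


def find_manifests(cohort_dir: str | Path) -> list[Path]:
    """All plan manifests under a cohort directory, sorted by sample id."""
    return sorted(Path(cohort_dir).glob("*_manifest.json"))
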