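"""Volumetric I/O, geometry validation and isotropic resampling.

Axis convention: arrays are indexed ``(z, y, x)`` with axial slices along the
first axis; ``spacing`` and ``origin`` follow the same order, in millimetres.
Voxel centers sit at ``origin + index * spacing`` (0-based indices, world mm).
NIfTI (.nii/.nii.gz) and NRRD (.nrrd) are supported through SimpleITK, whose
(x, y, z) header conventions are reversed at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
import SimpleITK as sitk

from .errors import (
    DegenerateLesionError,
    DimensionalityError,
    FormatError,
    GeometryError,
    ParameterError,
)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D CT scalar grid in Hounsfield units.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities (HU).
    spacing : tuple of 3 floats
        Voxel size in mm, ordered (z, y, x); all components > 0.
    origin : tuple of 3 floats
        World position (mm) of the voxel at index (0, 0, 0).
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise DimensionalityError(
                f"expected a 3D volume, got shape {arr.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.isfinite(arr).all():
            raise FormatError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask co-registered with a companion :class:`ImageVolume`."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise DimensionalityError(f"expected a 3D mask, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise FormatError(f"mask values must be in {{0, 1}}, found {uniq[:5]}")
        object.__setattr__(self, "data", arr.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SubjectStudy:
    """One subject: binary mutation label plus baseline and follow-up scans."""

    subject_id: str
    label: int  # 1 = sensitizing-mutant, 0 = wild-type
    pre: Tuple[ImageVolume, LesionMask]
    post: Tuple[ImageVolume, LesionMask]

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ParameterError(f"label must be 0 or 1, got {self.label}")
        validate_pair(*self.pre)
        validate_pair(*self.post)


# ---------------------------------------------------------------------------
# SimpleITK bridge


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing(tuple(reversed(spacing)))
    img.SetOrigin(tuple(reversed(origin)))
    return img


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported file type for {path}; expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path) -> ImageVolume:
    """Read a NIfTI or NRRD file into an :class:`ImageVolume`.

    Raises :class:`FormatError` on unreadable files and
    :class:`DimensionalityError` on non-3D payloads.
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all reader failures in RuntimeError
        raise FormatError(f"could not read {path}: header/payload unreadable ({exc})") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D payload, got {img.GetDimension()}D"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: payload decodes to shape {data.shape}")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return ImageVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def read_mask(path) -> LesionMask:
    """Read a binary lesion mask (values {0, 1}) from NIfTI or NRRD."""
    vol = read_volume(path)
    return LesionMask(data=vol.data, spacing=vol.spacing, origin=vol.origin)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume to NIfTI or NRRD, chosen by file suffix."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(volume.data, volume.spacing, volume.origin), str(path))


def write_mask(mask: LesionMask, path) -> None:
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(_to_sitk(mask.data, mask.spacing, mask.origin), str(path))


# ---------------------------------------------------------------------------
# Geometry


def validate_pair(volume: ImageVolume, mask: LesionMask, tol: float = 1e-6):
    """Check that a volume and mask share geometry and the mask is nonempty.

    Returns the pair unchanged; raises :class:`GeometryError` naming the
    mismatched field or :class:`DegenerateLesionError` for an empty mask.
    """
    if volume.shape != mask.shape:
        raise GeometryError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    for field in ("spacing", "origin"):
        v, m = getattr(volume, field), getattr(mask, field)
        if max(abs(a - b) for a, b in zip(v, m)) > tol:
            raise GeometryError(f"{field} mismatch: volume {v} vs mask {m}")
    if mask.n_foreground == 0:
        raise DegenerateLesionError("mask has no foreground voxels")
    return volume, mask


def resample_isotropic(
    volume: ImageVolume, mask: LesionMask, target_spacing: float
) -> Tuple[ImageVolume, LesionMask]:
    """Resample a volume/mask pair to isotropic ``target_spacing`` mm.

    The image is interpolated trilinearly, the mask by nearest neighbour so
    it stays binary; the world extent is preserved to within one voxel. The
    pair is returned unchanged when the grid is already isotropic at the
    target spacing.
    """
    if target_spacing <= 0:
        raise ParameterError(f"target_spacing must be > 0, got {target_spacing}")
    validate_pair(volume, mask)
    t = float(target_spacing)
    if all(abs(s - t) < 1e-12 for s in volume.spacing):
        return volume, mask

    old_size_xyz = tuple(reversed(volume.shape))
    old_spacing_xyz = tuple(reversed(volume.spacing))
    new_size = [
        max(1, int(round(n * s / t))) for n, s in zip(old_size_xyz, old_spacing_xyz)
    ]
    origin_xyz = tuple(reversed(volume.origin))

    def _resample(img: sitk.Image, interp) -> np.ndarray:
        out = sitk.Resample(
            img,
            new_size,
            sitk.Transform(),
            interp,
            origin_xyz,
            (t, t, t),
            img.GetDirection(),
            0.0,
            img.GetPixelID(),
        )
        return sitk.GetArrayFromImage(out)

    new_data = _resample(_to_sitk(volume.data, volume.spacing, volume.origin), sitk.sitkLinear)
    new_mask = _resample(_to_sitk(mask.data, mask.spacing, mask.origin), sitk.sitkNearestNeighbor)
    if new_mask.sum() == 0:
        raise DegenerateLesionError(
            f"lesion vanished when resampling to {t} mm (was {mask.n_foreground} voxels)"
        )
    spacing = (t, t, t)
    return (
        ImageVolume(data=new_data, spacing=spacing, origin=volume.origin),
        LesionMask(data=new_mask, spacing=spacing, origin=mask.origin),
    )


# ---------------------------------------------------------------------------
# Cohort manifest

MANIFEST_COLUMNS = ["subject_id", "label", "pre_image", "pre_mask", "post_image", "post_mask"]


def read_cohort_manifest(path) -> list:
    """Load a cohort from a manifest CSV.

    Columns: subject_id, label, pre_image, pre_mask, post_image, post_mask;
    paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    root = path.parent
    studies = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
        for row in reader:
            def load(col):
                p = Path(row[col])
                return p if p.is_absolute() else root / p

            studies.append(
                SubjectStudy(
                    subject_id=row["subject_id"],
                    label=int(row["label"]),
                    pre=(read_volume(load("pre_image")), read_mask(load("pre_mask"))),
                    post=(read_volume(load("post_image")), read_mask(load("post_mask"))),
                )
            )
    return studies


def write_cohort_manifest(studies, out_dir, fmt: str = ".nii.gz") -> Path:
    """Write a cohort as image/mask files plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "cohort.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for study in studies:
            names = {}
            for tp in ("pre", "post"):
                vol, msk = getattr(study, tp)
                vname = f"{study.subject_id}_{tp}_image{fmt}"
                mname = f"{study.subject_id}_{tp}_mask{fmt}"
                write_volume(vol, out_dir / vname)
                write_mask(msk, out_dir / mname)
                names[tp] = (vname, mname)
            writer.writerow(
                [study.subject_id, study.label, *names["pre"], *names["post"]]
            )
    return manifest
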