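"""Volume data model, geometry conventions, NIfTI/DICOM I/O and resampling.

Conventions
-----------
* Axis order is canonical: axis 0 = sagittal slice index (left-right),
  axis 1 = anterior-posterior, axis 2 = axial slice index (inferior-superior).
  Axial in-plane operations act on axes (0, 1); sagittal slices are
  ``data[i, :, :]``.
* Voxel indices are 0-based.  Physical coordinates are millimetres and map
  as ``world = origin + orientation @ (index * spacing)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelVolume",
    "GeometryError",
    "FormatError",
    "ValidationError",
    "MODALITY_TAGS",
    "modality_fill_value",
    "read_volume",
    "write_volume",
    "resample_to",
    "grids_match",
]

MODALITY_TAGS = ("CT", "MR_WATER", "MR_FAT", "MR_WFE", "MASK", "LABELS", "SCT")

#: Label codes for :class:`LabelVolume`.
LABEL_BACKGROUND = 0
LABEL_AIR_INSIDE = 1
LABEL_FAT = 2
LABEL_MUSCLE = 3
LABEL_BONE = 4
LABEL_CODES = (0, 1, 2, 3, 4)


class GeometryError(ValueError):
    """Invalid or inconsistent physical geometry."""


class FormatError(ValueError):
    """Unreadable or malformed file content."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


def _check_orientation(orientation: np.ndarray) -> np.ndarray:
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (3, 3):
        raise GeometryError(f"orientation must be 3x3, got {orientation.shape}")
    if not np.allclose(orientation.T @ orientation, np.eye(3), atol=1e-6):
        raise GeometryError("orientation columns are not orthonormal")
    if abs(abs(np.linalg.det(orientation)) - 1.0) > 1e-6:
        raise GeometryError("orientation determinant is not +-1")
    return orientation


@dataclass
class Volume:
    """A 3-D scalar grid with physical geometry.

    ``data`` carries HU for CT, arbitrary units for MR, and {0, 1} for masks.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality_tag: str = "MR_WATER"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3-D, got {self.data.ndim}-D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin.shape != (3,):
            raise GeometryError("origin must be a 3-vector")
        self.orientation = _check_orientation(self.orientation)
        if self.modality_tag not in MODALITY_TAGS:
            raise ValidationError(f"unknown modality tag {self.modality_tag!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")
        if self.modality_tag == "MASK":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError("mask volume must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine."""
        a = np.eye(4)
        a[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to physical mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx * self.spacing @ self.orientation.T + self.origin

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) physical mm coordinates to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.orientation / self.spacing

    def with_data(self, data: np.ndarray, modality_tag: str | None = None) -> "Volume":
        """New Volume on the same grid with replaced data."""
        return replace(
            self, data=data, modality_tag=modality_tag or self.modality_tag
        )

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass
class LabelVolume:
    """Integer tissue-label grid sharing a Volume's geometry.

    Codes: 0 background/outside air, 1 interior air, 2 fat, 3 muscle, 4 bone.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if not np.all(np.isin(np.unique(self.labels), LABEL_CODES)):
            raise ValidationError(f"labels outside the allowed set {LABEL_CODES}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = _check_orientation(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @classmethod
    def like(cls, v: Volume, labels: np.ndarray) -> "LabelVolume":
        return cls(labels=labels, spacing=v.spacing, origin=v.origin,
                   orientation=v.orientation)

    def as_volume(self, tag: str = "LABELS") -> Volume:
        return Volume(self.labels.astype(np.float32), self.spacing, self.origin,
                      self.orientation, tag)

    def mask(self, *codes: int) -> Volume:
        """Binary mask of the union of the given label codes."""
        m = np.isin(self.labels, codes).astype(np.uint8)
        return Volume(m, self.spacing, self.origin, self.orientation, "MASK")


def modality_fill_value(tag: str) -> float:
    """Out-of-support fill: air HU for CT-like volumes, 0 otherwise."""
    return -1000.0 if tag in ("CT", "SCT") else 0.0


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _from_nifti(img: nib.Nifti1Image, modality_tag: str) -> Volume:
    img = nib.as_closest_canonical(img)
    affine = img.affine
    rzs = affine[:3, :3]
    spacing = np.linalg.norm(rzs, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("non-positive voxel spacing in NIfTI header")
    orientation = rzs / spacing[np.newaxis, :]
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data=data, spacing=spacing, origin=affine[:3, 3],
                  orientation=orientation, modality_tag=modality_tag)


def read_volume(path: str | Path, modality_tag: str = "MR_WATER") -> Volume:
    """Read a NIfTI-1 file or a single-series DICOM directory as a Volume.

    CT rescale slope/intercept is applied on DICOM read so values are HU.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_dicom_series(path, modality_tag)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various subclasses
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is not a NIfTI image")
    return _from_nifti(img, modality_tag)


def _read_dicom_series(directory: Path, modality_tag: str) -> Volume:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError(
            "DICOM series reading requires the optional 'pydicom' package"
        ) from exc

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise FormatError(f"no readable DICOM files in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"mixed DICOM series in {directory}: {sorted(map(str, uids))}")

    # Sort by position along the slice normal.
    first = datasets[0]
    iop = np.array(first.ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)
    datasets.sort(key=lambda ds: float(np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices, axis=-1)  # (rows, cols, n_slices)

    ps = np.array(first.PixelSpacing, dtype=float)  # (row, col) mm
    if len(datasets) > 1:
        p0 = np.array(datasets[0].ImagePositionPatient, dtype=float)
        p1 = np.array(datasets[1].ImagePositionPatient, dtype=float)
        dz = float(np.linalg.norm(p1 - p0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    # pixel_array rows advance along `col` direction cosine, columns along `row`.
    data = np.transpose(stack, (1, 0, 2)).astype(np.float32)
    orientation = np.column_stack([row, col, normal])
    return Volume(data=data, spacing=np.array([ps[1], ps[0], dz]),
                  origin=np.array(first.ImagePositionPatient, dtype=float),
                  orientation=_check_orientation(orientation),
                  modality_tag=modality_tag)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 (float32 data; uint8 for masks)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if not np.all(np.isfinite(v.data)):
        raise ValidationError("refusing to write non-finite data")
    if v.modality_tag == "MASK":
        data = v.data.astype(np.uint8)
    elif v.modality_tag == "LABELS":
        data = v.data.astype(np.int16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = json.dumps({"modality": v.modality_tag}).encode()[:80]
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

_INTERP_ORDER = {"linear": 1, "nearest": 0}


def grids_match(a, b, atol: float = 1e-6) -> bool:
    """True when two volumes share shape, spacing, origin and orientation."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
        and np.allclose(a.orientation, b.orientation, atol=atol)
    )


def resample_to(v: Volume, reference: Volume, interpolation: str = "linear",
                fill: float | None = None) -> Volume:
    """Resample ``v`` onto ``reference``'s grid in physical space.

    Out-of-support voxels take the modality default (CT: -1000, else 0)
    unless ``fill`` overrides it.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if fill is None:
        fill = modality_fill_value(v.modality_tag)
    if grids_match(v, reference):
        return v.with_data(v.data.copy())

    # output index o -> input index i is affine: i = A @ o + b
    a_mat = (v.orientation.T @ reference.orientation) * reference.spacing[np.newaxis, :]
    a_mat = a_mat / v.spacing[:, np.newaxis]
    b_vec = (v.orientation.T @ (reference.origin - v.origin)) / v.spacing

    out = ndimage.affine_transform(
        v.data.astype(np.float64), a_mat, offset=b_vec,
        output_shape=reference.shape, order=_INTERP_ORDER[interpolation],
        mode="constant", cval=fill, prefilter=False,
    )
    if v.modality_tag == "MASK":
        out = (out > 0.5).astype(np.uint8) if interpolation == "linear" else out.astype(np.uint8)
    return Volume(out, reference.spacing, reference.origin, reference.orientation,
                  v.modality_tag)
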