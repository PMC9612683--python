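"""CT volume input/output and the coordinate conventions used everywhere else.

Conventions
-----------
* Arrays are indexed ``[z, y, x]`` — the first axis runs over axial slices,
  so a "slice index" always means an index into axis 0.
* ``spacing`` and ``origin`` are ``(z, y, x)`` tuples in millimetres.
* Indices are 0-based and refer to voxel *centres*: voxel ``(0, 0, 0)``
  sits exactly at ``origin``.
* Only axis-aligned volumes are supported.  DICOM series or NIfTI files
  whose direction matrix is not the identity are rejected — oblique gantry
  acquisitions are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom

HU_MIN = -1024
HU_MAX = 3071

#: label codes for ground-truth / annotation volumes
LABEL_BACKGROUND = 0
LABEL_PARENCHYMA = 1
LABEL_LUMEN = 2
LABEL_STONE = 3
LABEL_CODES = (LABEL_BACKGROUND, LABEL_PARENCHYMA, LABEL_LUMEN, LABEL_STONE)


class VolumeIOError(ValueError):
    """Raised for malformed volumes, inconsistent series, or bad headers."""


@dataclass
class CTVolume:
    """A 3-D scalar grid of Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        HU values; any signed numeric dtype.
    spacing : tuple of float
        Voxel spacing ``(dz, dy, dx)`` in mm, all positive.
    origin : tuple of float
        Physical position ``(z, y, x)`` in mm of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise VolumeIOError("bad dimensionality: expected a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError("spacing components must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def hu_int(self) -> np.ndarray:
        """Voxels rounded to integer HU (CT samples are integral by nature)."""
        return np.rint(self.voxels).astype(np.int32)


@dataclass
class LabelVolume:
    """Integer label map aligned with a :class:`CTVolume`.

    Codes: 0 background/fat, 1 parenchyma, 2 PCS lumen, 3 stone.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise VolumeIOError("bad dimensionality: expected a non-empty 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeIOError("label volume must have an integer dtype")
        bad = np.setdiff1d(np.unique(self.labels), np.asarray(LABEL_CODES))
        if bad.size:
            raise VolumeIOError(f"unknown label codes: {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeIOError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def world_to_voxel(vol: CTVolume | LabelVolume, point_mm: Sequence[float]) -> np.ndarray:
    """Map a physical ``(z, y, x)`` point in mm to continuous voxel indices.

    Points outside the grid are allowed; callers can check bounds via
    :func:`in_bounds`.
    """
    p = np.asarray(point_mm, dtype=float)
    return (p - np.asarray(vol.origin)) / np.asarray(vol.spacing)


def voxel_to_world(vol: CTVolume | LabelVolume, index: Sequence[float]) -> np.ndarray:
    """Map continuous voxel indices ``(i, j, k)`` to physical mm coordinates."""
    i = np.asarray(index, dtype=float)
    return i * np.asarray(vol.spacing) + np.asarray(vol.origin)


def in_bounds(vol: CTVolume | LabelVolume, index: Sequence[float]) -> bool:
    i = np.asarray(index, dtype=float)
    shape = vol.voxels.shape if isinstance(vol, CTVolume) else vol.labels.shape
    return bool(np.all(i > -0.5) and np.all(i < np.asarray(shape) - 0.5))


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    dz, dy, dx = spacing
    z0, y0, x0 = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = (x0, y0, z0)
    return aff


def write_volume(vol: CTVolume | LabelVolume, path: str | os.PathLike, format: str = "nifti") -> None:
    """Write a volume (or label map) to disk.

    Only NIfTI-1 output is supported.  Data are stored in ``x, y, z`` disk
    order with a diagonal affine so that a read round-trips voxels, spacing
    and origin exactly.
    """
    if format != "nifti":
        raise VolumeIOError(f"unsupported write format: {format!r}")
    arr = vol.voxels if isinstance(vol, CTVolume) else vol.labels
    img = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), _nifti_affine(vol.spacing, vol.origin))
    img.header.set_data_dtype(arr.dtype)
    nib.save(img, os.fspath(path))


def _read_nifti(path: str | os.PathLike) -> CTVolume:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError("bad dimensionality: NIfTI input must be a 3-D scalar volume")
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise VolumeIOError("only axis-aligned volumes are supported (non-diagonal affine)")
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise VolumeIOError("only positive-diagonal affines are supported")
    dx, dy, dz = diag
    x0, y0, z0 = aff[:3, 3]
    return CTVolume(
        voxels=np.transpose(data, (2, 1, 0)),
        spacing=(float(dz), float(dy), float(dx)),
        origin=(float(z0), float(y0), float(x0)),
    )


def read_labels(path: str | os.PathLike) -> LabelVolume:
    """Read a NIfTI label map written by :func:`write_volume`."""
    vol = _read_nifti(path)
    return LabelVolume(vol.voxels.astype(np.int16, copy=False), vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(path: str | os.PathLike) -> CTVolume:
    p = Path(path)
    files = sorted(f for f in p.iterdir() if f.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(os.fspath(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise VolumeIOError("inconsistent series: no readable DICOM slices found")

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    frames = {getattr(ds, "FrameOfReferenceUID", None) for ds in datasets}
    if len(series_uids) > 1 or len(frames) > 1:
        raise VolumeIOError("inconsistent series: mixed SeriesInstanceUID or frame of reference")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise VolumeIOError("inconsistent series: slices differ in matrix size")

    # sort by physical z ascending regardless of the on-disk file order
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    z_positions = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(datasets) > 1:
        steps = np.diff(z_positions)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-3):
            raise VolumeIOError("inconsistent series: non-uniform or duplicate slice positions")
        dz = float(steps[0])
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    dy, dx = (float(v) for v in datasets[0].PixelSpacing)  # row spacing, col spacing
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(slices, axis=0)
    if np.allclose(voxels, np.rint(voxels)):
        voxels = np.rint(voxels).astype(np.int16)
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return CTVolume(voxels=voxels, spacing=(dz, dy, dx), origin=origin)


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM stored values are rescaled to HU with the per-slice slope and
    intercept; slices are sorted by physical z ascending.

    Parameters
    ----------
    path : path
        ``.nii``/``.nii.gz`` file or a directory holding one DICOM series.
    format : {"nifti", "dicom_series"}, optional
        Inferred from ``path`` when omitted.
    """
    p = Path(path)
    if not p.exists():
        raise VolumeIOError(f"path does not exist: {p}")
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(p)
    if format == "dicom_series":
        return _read_dicom_series(p)
    raise VolumeIOError(f"unknown format: {format!r}")


def mask_to_label_volume(mask: np.ndarray, like: CTVolume, code: int = LABEL_LUMEN) -> LabelVolume:
    """Wrap a boolean mask as a LabelVolume aligned with ``like``."""
    arr = np.where(np.asarray(mask, bool), np.int16(code), np.int16(0))
    return LabelVolume(arr, like.spacing, like.origin)
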