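"""Volume, mask and seed-point I/O with a single grid convention.

Everything downstream of this module speaks one coordinate language:

* arrays are indexed ``(z, y, x)``, 0-based;
* ``spacing`` is ``(dz, dy, dx)`` in millimetres;
* a physical position is ``origin + index * spacing`` (mm).

Volumes and label images are exchanged as NIfTI-1 (``.nii``/``.nii.gz``) or
NRRD files; seed points travel in a small JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import AlignmentError, DimensionalityError, FormatError

__all__ = [
    "Volume",
    "BinaryMask",
    "SeedPoint",
    "read_volume",
    "write_volume",
    "read_annotation",
    "write_labels",
    "read_seed",
    "write_seed",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid in Hounsfield units with physical metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values (HU), stored as floats.
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in mm; all components positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise DimensionalityError(
                f"volume must be 3D with positive extents, got shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive components, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_point(self, index) -> np.ndarray:
        """Physical (z, y, x) position in mm of a voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask on the same grid as its parent :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got shape {data.shape}")
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0 or 1")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def sum(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SeedPoint:
    """A 0-based ``(z, y, x)`` voxel index, with optional case metadata."""

    index: tuple[int, int, int]
    case_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.index)
        if len(idx) != 3:
            raise ValueError("seed index must be (z, y, x)")
        object.__setattr__(self, "index", idx)

    def check_bounds(self, shape) -> None:
        for i, n in zip(self.index, shape):
            if not (0 <= i < n):
                raise IndexError(f"seed {self.index} outside volume shape {tuple(shape)}")


def _check_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(f"unsupported volume format: {path.name} "
                          f"(expected one of {_SUPPORTED_SUFFIXES})")


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    if img.GetDimension() != 3:
        raise DimensionalityError(f"expected a 3D image, got {img.GetDimension()}D")
    # SimpleITK arrays already come back (z, y, x); spacing/origin are (x, y, z).
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def read_volume(path) -> Volume:
    """Read a NIfTI or NRRD scalar volume, normalizing axes to (z, y, x).

    Raises
    ------
    FormatError
        If the file is missing, unreadable, or an unsupported format.
    DimensionalityError
        If the image is not three-dimensional.
    """
    path = Path(path)
    _check_path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all reader failures in RuntimeError
        raise FormatError(f"could not read {path}: {exc}") from exc
    arr, spacing, origin = _from_sitk(img)
    return Volume(arr.astype(np.float64), spacing, origin)


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` to NIfTI or NRRD (chosen by suffix)."""
    path = Path(path)
    _check_path(path)
    img = sitk.GetImageFromArray(np.asarray(volume.data, dtype=np.float64))
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    sitk.WriteImage(img, str(path))


def write_labels(labels: np.ndarray, like: Volume, path) -> None:
    """Write an integer label image on the grid of ``like``."""
    path = Path(path)
    _check_path(path)
    img = sitk.GetImageFromArray(np.asarray(labels, dtype=np.uint16))
    img.SetSpacing(tuple(reversed(like.spacing)))
    img.SetOrigin(tuple(reversed(like.origin)))
    sitk.WriteImage(img, str(path))


def read_annotation(path, volume: Volume) -> tuple[BinaryMask, BinaryMask]:
    """Read a label image and split it into (nodule, vessels) masks.

    The convention is label 1 = nodule, label 2 = attached vessels; any other
    value is background.

    Raises
    ------
    AlignmentError
        If the label image is not on the same grid as ``volume``.
    """
    path = Path(path)
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    arr, spacing, origin = _from_sitk(img)
    if arr.shape != volume.shape:
        raise AlignmentError(
            f"annotation shape {arr.shape} does not match volume shape {volume.shape}"
        )
    if not np.allclose(spacing, volume.spacing, atol=1e-4):
        raise AlignmentError(
            f"annotation spacing {spacing} does not match volume spacing {volume.spacing}"
        )
    labels = np.rint(arr).astype(np.int64)
    nodule = BinaryMask(labels == 1, volume.spacing, volume.origin)
    vessels = BinaryMask(labels == 2, volume.spacing, volume.origin)
    return nodule, vessels


def read_seed(path) -> SeedPoint:
    """Read a seed-point JSON sidecar.

    Expected keys: ``seed_zyx`` (required), ``case_id``, ``label``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    return SeedPoint(
        index=tuple(doc["seed_zyx"]),
        case_id=doc.get("case_id", ""),
        label=doc.get("label", ""),
    )


def write_seed(seed: SeedPoint, path) -> None:
    doc = {"case_id": seed.case_id, "seed_zyx": list(seed.index), "label": seed.label}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
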