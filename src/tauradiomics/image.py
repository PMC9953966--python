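"""Volume I/O, smoothing, resampling and mask algebra.

All downstream stages operate on three light containers: :class:`Volume`
(a 3D scalar grid with an affine), :class:`LabelMap` (an integer atlas with
a label-name lookup) and :class:`Mask` (boolean). Geometry is carried by the
NIfTI affine; voxel indices are 0-based, and any two images entering the same
computation must share shape and affine exactly — a mismatch raises instead
of silently resampling.

Internal computation is float64; files are written as float32 (labels as
int16/int32).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "Mask",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_lookup",
    "write_lookup",
    "gaussian_smooth",
    "resample_isotropic",
    "resample_labels_isotropic",
    "mask_from_labels",
    "check_same_geometry",
]

#: FWHM of a Gaussian = SIGMA_TO_FWHM * sigma
SIGMA_TO_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class GeometryError(ValueError):
    """Raised when two images that must share a grid do not."""


def _spacing_from_affine(affine: np.ndarray) -> Tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class Volume:
    """A 3D scalar image with voxel-to-world affine placement.

    Parameters
    ----------
    data:
        3D float array, arbitrary units (e.g. tracer uptake).
    affine:
        4x4 voxel-index-to-mm transform; voxel spacing is the column norm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> Tuple[float, float, float]:
        """Per-axis voxel size in mm."""
        return _spacing_from_affine(self.affine)

    def copy_with(self, data: np.ndarray) -> "Volume":
        """New Volume with the same geometry and different data."""
        return Volume(np.asarray(data, dtype=np.float64), self.affine.copy())


@dataclass
class LabelMap:
    """Integer-valued parcellation sharing geometry with paired Volumes.

    ``labels == 0`` is background; every nonzero label must appear in
    ``lookup`` (label id -> region name).
    """

    labels: np.ndarray
    affine: np.ndarray
    lookup: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integer-valued")
            self.labels = np.round(self.labels).astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"labels missing from lookup: {sorted(missing)}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    def ids(self) -> Tuple[int, ...]:
        """Sorted nonzero label ids actually present in the grid."""
        return tuple(int(v) for v in np.unique(self.labels) if v != 0)


@dataclass
class Mask:
    """Boolean ROI grid with the geometry of its source Volume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return _spacing_from_affine(self.affine)

    def count(self) -> int:
        return int(self.data.sum())


def check_same_geometry(*images, atol: float = 1e-5) -> None:
    """Raise :class:`GeometryError` unless all images share shape and affine."""
    ref = images[0]
    for im in images[1:]:
        if im.shape != ref.shape:
            raise GeometryError(f"shape mismatch: {im.shape} vs {ref.shape}")
        if not np.allclose(im.affine, ref.affine, atol=atol):
            raise GeometryError("affine mismatch between images")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Load a single-volume NIfTI file.

    4D inputs with singleton trailing dimensions are squeezed; more than
    three non-singleton dimensions is an error. Non-finite voxels are
    rejected (a masked analysis should carry the mask separately).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim > 3:
        raise ValueError(
            f"{path}: expected a single 3D volume, got shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite voxel values after load")
    return Volume(data, np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    """Write a Volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_labelmap(path, lookup_path=None) -> LabelMap:
    """Load an integer label map; lookup from a 2-column TSV if given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim > 3:
        raise ValueError(f"{path}: label map must be 3D, got shape {data.shape}")
    labels = np.round(np.asarray(data, dtype=np.float64)).astype(np.int32)
    if lookup_path is not None:
        lookup = read_lookup(lookup_path)
    else:
        lookup = {int(v): f"region_{int(v):03d}" for v in np.unique(labels) if v != 0}
    return LabelMap(labels, np.asarray(img.affine), lookup)


def write_labelmap(lm: LabelMap, path, lookup_path=None) -> None:
    img = nib.Nifti1Image(lm.labels.astype(np.int32), lm.affine)
    nib.save(img, str(path))
    if lookup_path is not None:
        write_lookup(lm.lookup, lookup_path)


def read_lookup(path) -> Dict[int, str]:
    """Read a label lookup TSV (label_id <tab> region_name), header optional."""
    lookup: Dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        try:
            lid = int(parts[0])
        except ValueError:
            continue  # header row
        lookup[lid] = parts[1] if len(parts) > 1 else str(lid)
    return lookup


def write_lookup(lookup: Dict[int, str], path) -> None:
    lines = ["label_id\tregion_name"]
    for lid in sorted(lookup):
        lines.append(f"{lid}\t{lookup[lid]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def gaussian_smooth(vol: Volume, fwhm_mm: float = 8.0, mode: str = "nearest") -> Volume:
    """Gaussian smoothing with the kernel width given as FWHM in mm.

    Per-axis sigma (in voxels) is ``fwhm_mm / SIGMA_TO_FWHM / spacing_axis``.
    Boundary handling defaults to nearest-edge replication, which conserves
    total intensity away from the grid boundary.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm / SIGMA_TO_FWHM / s for s in vol.spacing]
    return vol.copy_with(ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode=mode))


def _iso_affine(affine: np.ndarray, iso_mm: float) -> np.ndarray:
    """Affine for the isotropic grid: unit direction columns scaled to iso_mm."""
    new = affine.copy()
    for i in range(3):
        col = affine[:3, i]
        new[:3, i] = col / np.linalg.norm(col) * iso_mm
    return new


def _iso_coords(shape, spacing, iso_mm):
    """Output shape and the sampling coordinates (in input voxel index units).

    Both grids share the first voxel center; the output grid covers the same
    physical extent (index range 0 .. (n-1)*spacing mm per axis).
    """
    new_shape = []
    axes = []
    for n, sp in zip(shape, spacing):
        extent = (n - 1) * sp
        m = int(np.floor(extent / iso_mm + 1e-9)) + 1
        if m < 1:
            raise GeometryError("degenerate extent for requested spacing")
        new_shape.append(m)
        axes.append(np.arange(m) * iso_mm / sp)
    grids = np.meshgrid(*axes, indexing="ij")
    return tuple(new_shape), np.stack([g.ravel() for g in grids])


def resample_isotropic(vol: Volume, iso_mm: float = 2.0) -> Volume:
    """Trilinear resampling onto an isotropic grid covering the same extent.

    A volume already on an (iso, iso, iso) grid is returned with identical
    data (the sampling points coincide with the input voxel centers).
    """
    if iso_mm <= 0:
        raise ValueError("iso_mm must be positive")
    sp = vol.spacing
    if np.allclose(sp, iso_mm):
        return Volume(vol.data.copy(), vol.affine.copy())
    new_shape, coords = _iso_coords(vol.shape, sp, iso_mm)
    out = ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest")
    return Volume(out.reshape(new_shape), _iso_affine(vol.affine, iso_mm))


def resample_labels_isotropic(lm: LabelMap, iso_mm: float = 2.0) -> LabelMap:
    """Nearest-neighbor variant of :func:`resample_isotropic` for label maps."""
    if iso_mm <= 0:
        raise ValueError("iso_mm must be positive")
    sp = lm.spacing
    if np.allclose(sp, iso_mm):
        return LabelMap(lm.labels.copy(), lm.affine.copy(), dict(lm.lookup))
    new_shape, coords = _iso_coords(lm.shape, sp, iso_mm)
    out = ndimage.map_coordinates(lm.labels, coords, order=0, mode="nearest")
    return LabelMap(out.reshape(new_shape), _iso_affine(lm.affine, iso_mm), dict(lm.lookup))


def mask_from_labels(lm: LabelMap, ids: Iterable[int]) -> Mask:
    """Boolean mask of voxels whose label is in ``ids``.

    ``ids`` must be a nonempty subset of the lookup keys.
    """
    ids = set(int(i) for i in ids)
    if not ids:
        raise ValueError("empty label selection")
    unknown = ids - set(lm.lookup)
    if unknown:
        raise KeyError(f"unknown label ids: {sorted(unknown)}")
    return Mask(np.isin(lm.labels, sorted(ids)), lm.affine.copy())
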