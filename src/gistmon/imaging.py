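"""NIfTI ingestion and the voxel-grid contract shared by every metric.

CT volumes carry attenuation in Hounsfield units (HU); lesion masks are
binary volumes of interest (VOIs) on the same grid.  Physical positions are
voxel centres at ``index * spacing`` with 0-based indices.  One axis of the
grid is designated *axial* (the anatomical inferior-superior direction);
slices perpendicular to it are the transaxial planes on which RECIST
diameters are measured.  On reading, the axial axis is inferred from the
NIfTI affine; when orientation metadata is unusable the reader falls back
to array axis 2 and logs a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ImageGrid",
    "CTVolume",
    "LesionMask",
    "FormatError",
    "AlignmentError",
    "read_volume",
    "read_mask",
    "write_mask",
    "write_volume",
]


class FormatError(ValueError):
    """The file is not a usable 3-D image (wrong rank, bad spacing, ...)."""


class AlignmentError(ValueError):
    """Two images that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3-D voxel lattice with physical spacing and a designated axial axis.

    Parameters
    ----------
    shape
        Voxels per array axis.
    spacing
        Millimetres per voxel along each array axis; all components must be
        strictly positive.
    axial_axis
        Index of the array axis aligned with the inferior-superior
        direction.  Slices of constant index along this axis are the
        transaxial planes.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    axial_axis: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise FormatError(f"grid must be 3-D, got shape={self.shape} spacing={self.spacing}")
        if any(s <= 0 for s in self.shape):
            raise FormatError(f"non-positive shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"non-positive spacing {self.spacing}")
        if self.axial_axis not in (0, 1, 2):
            raise FormatError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def in_plane_axes(self) -> tuple[int, int]:
        """The two array axes spanning a transaxial slice."""
        return tuple(a for a in (0, 1, 2) if a != self.axial_axis)  # type: ignore[return-value]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        a, b = self.in_plane_axes
        return (self.spacing[a], self.spacing[b])

    def matches(self, other: "ImageGrid", tol_mm: float = 1e-3) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing)
        )


@dataclass
class CTVolume:
    """A scalar HU field over an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise FormatError(
                f"intensity shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class LesionMask:
    """A binary VOI over an :class:`ImageGrid` (1 = tumour voxel)."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.shape != self.grid.shape:
            raise FormatError(f"mask shape {arr.shape} != grid shape {self.grid.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be {{0,1}}, found {uniq[:5]}")
        self.values = arr.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0


def _axial_axis_from_affine(affine: np.ndarray | None) -> int:
    """Array axis most aligned with the anatomical S/I direction.

    Falls back to axis 2 (with a warning) when the affine is missing or
    degenerate, which keeps synthetic data with default headers usable.
    """
    if affine is None:
        log.warning("no orientation affine; assuming axial axis = 2")
        return 2
    try:
        ornt = nib.orientations.io_orientation(np.asarray(affine, dtype=float))
        axial = int(np.where(ornt[:, 0] == 2)[0][0])
        return axial
    except Exception:  # singular / NaN affines
        log.warning("unusable orientation affine; assuming axial axis = 2")
        return 2


def _affine_for(grid: ImageGrid) -> np.ndarray:
    """A diagonal-up-to-permutation RAS affine encoding spacing and axial axis."""
    rows = {grid.axial_axis: 2}
    remaining = iter(a for a in (0, 1) if True)
    for j in (0, 1, 2):
        if j not in rows:
            rows[j] = next(remaining)
    affine = np.zeros((4, 4))
    for j in (0, 1, 2):
        affine[rows[j], j] = grid.spacing[j]
    affine[3, 3] = 1.0
    return affine


def _load_3d(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    axial = _axial_axis_from_affine(img.affine)
    grid = ImageGrid(shape=data.shape, spacing=tuple(float(z) for z in zooms), axial_axis=axial)
    return data, grid


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume (HU) from a NIfTI file."""
    data, grid = _load_3d(path)
    return CTVolume(grid=grid, values=data.astype(np.float64))


def read_mask(path: str | Path, reference: ImageGrid | None = None) -> LesionMask:
    """Read a binary lesion mask, binarizing any nonzero voxel to 1.

    When ``reference`` is given, the mask grid must match it in shape and
    spacing (1e-3 mm tolerance); the reference's axial axis is adopted so
    downstream diameters are measured in the same plane as the CT.
    """
    data, grid = _load_3d(path)
    if reference is not None:
        if not grid.matches(reference):
            raise AlignmentError(
                f"mask grid shape={grid.shape} spacing={grid.spacing} does not match "
                f"reference shape={reference.shape} spacing={reference.spacing}"
            )
        grid = reference
    return LesionMask(grid=grid, values=(data != 0).astype(np.uint8))


def write_mask(mask: LesionMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI; round-trip reads reproduce voxels exactly."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_for(mask.grid))
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def write_volume(ct: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(ct.values.astype(np.float32), _affine_for(ct.grid))
    img.header.set_zooms(ct.grid.spacing)
    nib.save(img, str(path))
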