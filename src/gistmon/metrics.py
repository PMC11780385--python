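"""Per-scan lesion metrics: volume, longest transaxial diameter, mean density.

These are the three scalars the response criteria consume.  Volume is the
tumour voxel count times the physical voxel volume.  The diameter is the
longest in-plane distance between tumour voxel centres over all transaxial
slices (the RECIST committee recommends measuring in the axial plane, so no
3-D chord is ever taken).  Density is the arithmetic mean HU over the VOI
with no trimming.  The Dice similarity coefficient (DSC) compares two
delineations of the same lesion for interobserver analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .imaging import AlignmentError, CTVolume, ImageGrid, LesionMask

__all__ = [
    "LesionObservation",
    "EmptyMaskError",
    "compute_volume",
    "longest_transaxial_diameter",
    "mean_density",
    "dice",
    "percent_change",
    "observe",
]


class EmptyMaskError(ValueError):
    """An operation that needs tumour voxels was given an empty mask."""


@dataclass(frozen=True)
class LesionObservation:
    """Scalar lesion metrics for one scan.

    ``present`` is False when the lesion is undetectable, in which case
    volume and diameter are zero and density is undefined (``None``).
    ``month`` is months from the baseline scan.
    """

    present: bool
    volume_mm3: float
    diameter_mm: float
    density_hu: float | None = None
    month: float = 0.0

    def __post_init__(self) -> None:
        if self.month < 0:
            raise ValueError(f"negative month offset {self.month}")
        if self.volume_mm3 < 0 or self.diameter_mm < 0:
            raise ValueError("volume and diameter must be non-negative")
        if self.present != (self.volume_mm3 > 0):
            raise ValueError(
                f"present={self.present} inconsistent with volume {self.volume_mm3}"
            )
        if not self.present and self.diameter_mm != 0:
            raise ValueError("absent lesion must have zero diameter")


def compute_volume(mask: LesionMask) -> float:
    """Tumour volume in mm^3 (voxel count x voxel volume); 0 for empty masks."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest Euclidean distance between any two 2-D points.

    For larger point sets the diameter endpoints must lie on the convex
    hull, so the all-pairs search is restricted to hull vertices; degenerate
    (collinear) slices fall back to the direct computation.
    """
    n = len(points)
    if n < 2:
        return 0.0
    if n > 16:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass
    return float(pdist(points).max())


def longest_transaxial_diameter(mask: LesionMask) -> float:
    """Longest in-plane diameter over all transaxial slices, in mm.

    Within each slice perpendicular to the axial axis, computes the maximum
    distance between tumour voxel centres using the in-plane spacing, then
    takes the maximum over slices.  Empty and single-voxel masks have zero
    extent between centres and return 0.
    """
    grid = mask.grid
    coords = np.argwhere(mask.values != 0)
    if len(coords) < 2:
        return 0.0
    ia, ib = grid.in_plane_axes
    scale = np.array(grid.in_plane_spacing)
    best = 0.0
    for z in np.unique(coords[:, grid.axial_axis]):
        in_slice = coords[coords[:, grid.axial_axis] == z]
        pts = in_slice[:, (ia, ib)].astype(float) * scale
        best = max(best, _max_pairwise_distance(pts))
    return best


def mean_density(ct: CTVolume, mask: LesionMask) -> float:
    """Arithmetic mean HU over the VOI; raises on an empty mask."""
    if not ct.grid.matches(mask.grid):
        raise AlignmentError(
            f"CT grid {ct.grid.shape}/{ct.grid.spacing} does not match "
            f"mask grid {mask.grid.shape}/{mask.grid.spacing}"
        )
    if mask.is_empty:
        raise EmptyMaskError("mean density is undefined for an empty mask")
    return float(ct.values[mask.values != 0].mean())


def dice(a: LesionMask, b: LesionMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Defined as 1.0 when both masks are empty (agreement on absence).
    """
    if not a.grid.matches(b.grid):
        raise AlignmentError("masks must share a grid for Dice comparison")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def percent_change(baseline: float, follow: float) -> float:
    """100 x (follow - baseline) / baseline; negative values are reductions."""
    if baseline == 0:
        raise ValueError("percent change is undefined for a zero baseline")
    return 100.0 * (follow - baseline) / baseline


def observe(
    mask: LesionMask, ct: CTVolume | None = None, month: float = 0.0
) -> LesionObservation:
    """Bundle the per-scan metrics of one mask into a LesionObservation."""
    vol = compute_volume(mask)
    present = vol > 0
    density = None
    if present and ct is not None:
        density = mean_density(ct, mask)
    return LesionObservation(
        present=present,
        volume_mm3=vol,
        diameter_mm=longest_transaxial_diameter(mask) if present else 0.0,
        density_hu=density,
        month=month,
    )
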