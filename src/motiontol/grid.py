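"""Geometry primitives: dose grids, binary masks, trilinear sampling, overlap volumes.

All coordinates are DICOM patient LPS (x = patient-left, y = patient-posterior,
z = patient-superior), in millimetres.  Voxel indices are 0-based and refer to
voxel centers: the center of voxel (i, j, k) sits at ``origin + (i, j, k) * spacing``.
Dose is in Gy, volumes in cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import map_coordinates


class GeometryMismatchError(ValueError):
    """Raised when two gridded objects do not share the same geometry."""


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned 3D grid in patient LPS coordinates.

    Parameters
    ----------
    origin : (3,) array-like, mm
        Patient coordinates of the center of voxel (0, 0, 0).
    spacing : (3,) array-like, mm
        Voxel spacing along (x, y, z); all components strictly positive.
    dims : (3,) array-like of int
        Number of voxels along (x, y, z).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"dims must be positive, got {self.dims}")

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape, (nx, ny, nz)."""
        return self.dims

    def voxel_centers(self) -> np.ndarray:
        """Return an (N, 3) array of voxel-center coordinates in C order."""
        ax = [self.origin[a] + self.spacing[a] * np.arange(self.dims[a]) for a in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=x, 1=y, 2=z)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of patient-coordinate points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class DoseGrid:
    """A static 3D dose field (Gy) on an axis-aligned grid."""

    geometry: GridGeometry
    values: np.ndarray
    #: number of out-of-grid lookups in the most recent sampling call
    oob_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"dose array shape {self.values.shape} != geometry dims {self.geometry.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")


@dataclass
class BinaryMask:
    """A voxelized structure: one boolean per voxel of its geometry."""

    geometry: GridGeometry
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.bits.shape} != geometry dims {self.geometry.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.bits.sum()) * self.geometry.voxel_volume_cc

    def voxel_centers(self) -> np.ndarray:
        """Patient coordinates of the centers of all true voxels, (N, 3)."""
        idx = np.argwhere(self.bits).astype(float)
        return np.asarray(self.geometry.origin) + idx * np.asarray(self.geometry.spacing)


class Direction(Enum):
    """The six cardinal anatomical directions, as unit vectors in LPS."""

    LEFT = (1.0, 0.0, 0.0)
    RIGHT = (-1.0, 0.0, 0.0)
    ANT = (0.0, -1.0, 0.0)
    POST = (0.0, 1.0, 0.0)
    SUP = (0.0, 0.0, 1.0)
    INF = (0.0, 0.0, -1.0)

    @property
    def unit_vector(self) -> np.ndarray:
        return np.asarray(self.value, dtype=float)

    @property
    def opposite(self) -> "Direction":
        return _OPPOSITE[self]


_OPPOSITE = {
    Direction.LEFT: Direction.RIGHT,
    Direction.RIGHT: Direction.LEFT,
    Direction.ANT: Direction.POST,
    Direction.POST: Direction.ANT,
    Direction.SUP: Direction.INF,
    Direction.INF: Direction.SUP,
}


def sample_trilinear(dose: DoseGrid, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate the dose field at patient-coordinate points.

    Points outside the voxel-center bounding box return 0 Gy; the number of
    such points is recorded on ``dose.oob_count`` (fail-soft with
    observability rather than an error).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = dose.geometry.point_to_index(pts)  # fractional indices, (N, 3)
    dims = np.asarray(dose.geometry.dims)
    inside = np.all((idx >= 0) & (idx <= dims - 1), axis=1)
    dose.oob_count = int((~inside).sum())
    out = map_coordinates(dose.values, idx.T, order=1, mode="constant", cval=0.0)
    out[~inside] = 0.0
    return out


def threshold_mask(dose: DoseGrid, level: float) -> BinaryMask:
    """Voxels with dose >= level (closed bound, so V_D counts dose exactly D)."""
    if level < 0:
        raise ValueError("threshold level must be >= 0")
    return BinaryMask(dose.geometry, dose.values >= level)


def overlap_volume(a: BinaryMask, b: BinaryMask) -> float:
    """Volume (cc) of the voxelwise Boolean AND of two masks on one grid."""
    if a.geometry != b.geometry:
        raise GeometryMismatchError(
            f"masks live on different grids: {a.geometry} vs {b.geometry}"
        )
    return float(np.count_nonzero(a.bits & b.bits)) * a.geometry.voxel_volume_cc


def translate_points(points: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Exact continuous translation of points by a 3-vector (mm)."""
    return np.atleast_2d(np.asarray(points, dtype=float)) + np.asarray(vector, dtype=float)
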