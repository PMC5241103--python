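"""Grid-aware volume and mask containers.

All volumes in this package live on a regular, axis-aligned 3D grid with
anisotropic physical spacing. World coordinates are millimetres at voxel
centers; voxel indices are 0-based; the axis convention is right-handed
with grid axes aligned to world axes (RAS-like). Volumes loaded from disk
are reoriented into this convention before anything else touches them,
which removes the usual source of overlap/margin bugs when two
acquisition grids (a ~1 mm clinical grid and a 4.4 x 4.4 x 5.6 mm
spectroscopic grid) are mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = ["VolumeGrid", "ScalarMap", "Mask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when an operation requires two volumes to share a grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a regular 3D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis; each entry >= 1.
    spacing
        Physical voxel size in mm along each axis; strictly positive.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("VolumeGrid is strictly 3D")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal by convention)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of world points."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of world coordinates of all voxel centers."""
        return np.meshgrid(
            self.axis_coordinates(0),
            self.axis_coordinates(1),
            self.axis_coordinates(2),
            indexing="ij",
        )

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world corners of the grid's voxel-edge bounding box."""
        sp = np.asarray(self.spacing)
        og = np.asarray(self.origin)
        lo = og - 0.5 * sp
        hi = og + (np.asarray(self.shape) - 0.5) * sp
        return lo, hi

    def close_to(self, other: "VolumeGrid", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(a, b, what: str = "operation"):
    ga = a.grid if hasattr(a, "grid") else a
    gb = b.grid if hasattr(b, "grid") else b
    if not ga.close_to(gb):
        raise GridMismatchError(
            f"{what} requires both volumes on the same grid "
            f"(got shapes {ga.shape} vs {gb.shape}, spacings {ga.spacing} vs "
            f"{gb.spacing}); resample explicitly first"
        )


@dataclass
class ScalarMap:
    """A scalar field (metabolite signal, fold-normal ratio, or dose in Gy)
    on a :class:`VolumeGrid`.

    Invalid voxels (no signal, outside interpolation support, NAA at the
    division floor, ...) are flagged in the companion boolean ``valid``
    array rather than encoded as sentinel values, so reference-region
    statistics exclude them instead of diluting them.
    """

    grid: VolumeGrid
    values: np.ndarray
    unit: str = "arbitrary-signal"  # arbitrary-signal | fold-normal | Gy
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("valid mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite values inside the validity mask")

    def copy(self) -> "ScalarMap":
        return ScalarMap(self.grid, self.values.copy(), self.unit, self.valid.copy())


@dataclass
class Mask:
    """A binary region (target volume, organ, NAWM, recurrence, ...)."""

    grid: VolumeGrid
    data: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.count * self.grid.voxel_volume_cm3

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def copy(self, label: Optional[str] = None) -> "Mask":
        return Mask(self.grid, self.data.copy(), self.label if label is None else label)

    # set algebra, grid-checked
    def union(self, other: "Mask", label: str = "") -> "Mask":
        _require_same_grid(self, other, "union")
        return Mask(self.grid, self.data | other.data, label)

    def intersection(self, other: "Mask", label: str = "") -> "Mask":
        _require_same_grid(self, other, "intersection")
        return Mask(self.grid, self.data & other.data, label)

    def difference(self, other: "Mask", label: str = "") -> "Mask":
        _require_same_grid(self, other, "difference")
        return Mask(self.grid, self.data & ~other.data, label)

    def issubset(self, other: "Mask") -> bool:
        _require_same_grid(self, other, "subset test")
        return bool(np.all(~self.data | other.data))
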