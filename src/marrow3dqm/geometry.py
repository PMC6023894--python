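"""Core voxel-geometry containers shared by every stage of the pipeline.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)`` (plane-major, as confocal stacks are
  stored) and voxel spacing is given in the same order, in micrometres.
* The physical coordinate of voxel index ``(k, j, i)`` is the voxel
  *center* ``((k + 0.5) dz, (j + 0.5) dy, (i + 0.5) dx)`` in µm.
* Volumes are computed from voxel counts only — the number of foreground
  voxels times the voxel volume — with no sub-voxel surface correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "VolumetricImage",
    "BinaryMask",
    "PointSet",
    "DistanceField",
    "voxel_volume",
    "mask_volume",
    "MM3_PER_UM3",
    "GeometryError",
    "IncompatibleGridError",
]

#: 1 mm³ = 10⁹ µm³ (= 1 µL)
MM3_PER_UM3 = 1e-9

MASK_ROLES = frozenset(
    {"tissue", "vessel", "network", "bone", "marrow", "domain"}
)


class GeometryError(ValueError):
    """Invalid voxel geometry (non-positive spacing or shape)."""


class IncompatibleGridError(ValueError):
    """Two objects that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular anisotropic 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (z, y, x); all positive.
    spacing : tuple of float
        Voxel edge lengths (dz, dy, dx) in µm; all strictly positive.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise GeometryError("grid shape and spacing must be 3-vectors (z, y, x)")
        if any(s <= 0 for s in shape):
            raise GeometryError(f"grid shape must be positive, got {shape}")
        if not all(np.isfinite(spacing)) or any(s <= 0 for s in spacing):
            raise GeometryError(f"voxel spacing must be positive and finite, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid box in µm."""
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Map integer voxel indices (n, 3) to physical center coordinates (µm)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.spacing)

    def nearest_voxel(self, coords: np.ndarray) -> np.ndarray:
        """Map physical µm coordinates (n, 3) to the index of the containing voxel.

        Coordinates are clipped to the grid so points on the outer face map
        to the last voxel.
        """
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        idx = np.floor(pts / np.asarray(self.spacing)).astype(int)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean per point: does the physical coordinate lie inside the box?"""
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        ext = np.asarray(self.physical_extent)
        return np.all((pts >= 0) & (pts <= ext), axis=1)


def _check_values(grid: VoxelGrid, values: np.ndarray, name: str) -> None:
    if tuple(values.shape) != grid.shape:
        raise IncompatibleGridError(
            f"{name} array shape {values.shape} does not match grid shape {grid.shape}"
        )


@dataclass
class VolumetricImage:
    """A single-channel 3D scalar intensity field on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_values(self.grid, self.values, "image")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing


@dataclass
class BinaryMask:
    """A 3D boolean field on a grid, tagged by its biological role."""

    grid: VoxelGrid
    values: np.ndarray
    role: str = "domain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        _check_values(self.grid, self.values, "mask")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {sorted(MASK_ROLES)}")

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 * MM3_PER_UM3

    def same_grid(self, other: "BinaryMask | VolumetricImage | DistanceField") -> bool:
        return self.grid == other.grid


@dataclass
class PointSet:
    """Cell centroids in physical µm coordinates (z, y, x).

    ``radius`` is an optional shared soma radius in µm; ``labels`` an
    optional per-point category (e.g. ``peri`` / ``non_peri``).
    """

    coords: np.ndarray
    radius: Optional[float] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("point coordinates must be finite")
        if self.radius is not None and self.radius < 0:
            raise ValueError("radius must be >= 0")
        self.coords = coords
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(coords):
                raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def subset(self, keep: np.ndarray) -> "PointSet":
        labels = self.labels[keep] if self.labels is not None else None
        return PointSet(self.coords[keep], radius=self.radius, labels=labels)


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance (µm) to a target structure.

    Values are defined only where ``domain`` is true; elsewhere they are
    NaN. ``on_target`` flags domain voxels lying on/inside the target
    (distance exactly 0), which downstream statistics typically exclude.
    """

    grid: VoxelGrid
    domain: BinaryMask
    values: np.ndarray
    target_role: str = ""
    on_target: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_values(self.grid, self.values, "distance field")
        if self.domain.grid != self.grid:
            raise IncompatibleGridError("distance-field domain grid differs from field grid")
        if self.on_target is None:
            self.on_target = np.zeros(self.grid.shape, dtype=bool)
        inside = self.values[self.domain.values]
        if inside.size and (np.nanmin(inside) < 0):
            raise ValueError("distances must be non-negative on the domain")

    def domain_values(self, exclude_target_interior: bool = False) -> np.ndarray:
        """Flat array of distances over the domain voxels."""
        sel = self.domain.values
        if exclude_target_interior:
            sel = sel & ~self.on_target
        return self.values[sel]

    def sample_at(self, points: PointSet) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-voxel lookup of the field at physical point coordinates.

        Returns ``(distances, in_domain)``; distances are NaN for points
        whose containing voxel is outside the domain.
        """
        idx = self.grid.nearest_voxel(points.coords)
        k, j, i = idx[:, 0], idx[:, 1], idx[:, 2]
        in_domain = self.domain.values[k, j, i] & self.grid.contains(points.coords)
        out = np.where(in_domain, self.values[k, j, i], np.nan)
        return out, in_domain


def voxel_volume(grid: VoxelGrid) -> float:
    """Volume of a single voxel, dz·dy·dx in µm³."""
    return grid.voxel_volume


def mask_volume(mask: BinaryMask, units: str = "um3") -> float:
    """Volume of a binary mask: foreground voxel count × voxel volume.

    Parameters
    ----------
    mask : BinaryMask
    units : {"um3", "mm3"}
        ``mm3`` (= µL) divides by 10⁹.
    """
    v = mask.volume_um3
    if units == "um3":
        return v
    if units == "mm3":
        return v * MM3_PER_UM3
    raise ValueError(f"unknown units {units!r}")
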