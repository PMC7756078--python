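"""Voxel-grid primitives shared by all pipeline stages.

A grid is a regular 3-D lattice of voxel centers. World coordinates are in
millimetres; ``origin`` is the world position of the center of voxel
``(0, 0, 0)`` and axes are ordered (x, y, z) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "Mask", "DoseGrid", "mask_volume"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel lattice: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positives, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size covered by voxel centers along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) of voxel centers."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world positions (..., 3) to fractional index coordinates."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
    ) -> "GridSpec":
        """Grid whose world origin sits at the lattice center."""
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(tuple(shape), tuple(spacing), origin)


def _check_grid(grid: GridSpec, values: np.ndarray, what: str) -> None:
    if tuple(values.shape) != tuple(grid.shape):
        raise ValueError(
            f"{what} array shape {values.shape} does not match grid {grid.shape}"
        )


@dataclass
class Mask:
    """Binary structure mask on a grid."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        _check_grid(self.grid, self.values, "mask")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return mask_volume(self)

    def centroid_mm(self) -> np.ndarray:
        """World-coordinate centroid of the masked voxel centers."""
        if self.voxel_count == 0:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.values)
        mean_idx = idx.mean(axis=0)
        return np.asarray(self.grid.origin) + mean_idx * np.asarray(self.grid.spacing)

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.grid, self.values & other.values)

    def __or__(self, other: "Mask") -> "Mask":
        return Mask(self.grid, self.values | other.values)

    def __sub__(self, other: "Mask") -> "Mask":
        return Mask(self.grid, self.values & ~other.values)


@dataclass
class DoseGrid:
    """Dose distribution in Gy on a grid; non-negative and finite."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_grid(self.grid, self.values, "dose")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("dose contains negative values")

    def in_mask(self, mask: Mask) -> np.ndarray:
        """Flat array of voxel doses inside ``mask``."""
        if mask.grid != self.grid:
            raise ValueError("mask and dose are on different grids")
        return self.values[mask.values]


def mask_volume(mask: Mask) -> float:
    """Structure volume in cm³: voxel count × voxel volume."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3 / 1000.0
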