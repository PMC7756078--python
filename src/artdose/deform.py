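"""Analytic deformation vector fields (DVFs) for tumor contraction.

Convention (pull-back): a DVF lives on the planning grid and maps a
planning-frame point x to its fraction-frame position x + u(x).  Warping a
fraction-frame image into the planning frame therefore samples it at x + u(x).

The contraction field models isotropic tumor shrinkage about the GTV centroid:
u(x) = (s − 1)·(x − c) inside the planning GTV (s = linear scale, c =
centroid), tapered smoothly to zero over ``support_mm`` outside the GTV so
that nearby normal tissue is dragged inward while the far field stays rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec, Mask

__all__ = ["DVF", "make_contraction_dvf", "identity_dvf", "warp_mask", "invert_dvf"]


@dataclass
class DVF:
    """Displacement field u(x) in mm on the planning grid, shape (*grid, 3)."""

    grid: GridSpec
    displacement: np.ndarray = field(repr=False)
    max_displacement_mm: float = 100.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if tuple(self.displacement.shape) != tuple(self.grid.shape) + (3,):
            raise ValueError(
                f"displacement shape {self.displacement.shape} must be "
                f"{tuple(self.grid.shape) + (3,)}"
            )
        mag = np.linalg.norm(self.displacement, axis=-1).max() if \
            self.displacement.size else 0.0
        if mag > self.max_displacement_mm:
            raise ValueError(
                f"displacement magnitude {mag:.1f} mm exceeds the configured "
                f"maximum {self.max_displacement_mm} mm"
            )

    @property
    def is_identity(self) -> bool:
        return not self.displacement.any()

    def sample_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate u at world positions (..., 3)."""
        idx = self.grid.world_to_index(points_mm)
        coords = np.moveaxis(idx, -1, 0)
        out = np.empty(points_mm.shape, dtype=float)
        for k in range(3):
            out[..., k] = ndimage.map_coordinates(
                self.displacement[..., k], coords, order=1, mode="nearest"
            )
        return out


def identity_dvf(grid: GridSpec) -> DVF:
    return DVF(grid, np.zeros(tuple(grid.shape) + (3,)))


def make_contraction_dvf(
    planning_gtv: Mask,
    fraction_gtv: Mask,
    support_mm: float = 40.0,
) -> DVF:
    """Radial contraction field carrying the planning GTV onto the fraction GTV.

    The linear scale is the cube root of the volume ratio; the field is exact
    inside the planning GTV and decays with a smooth cosine taper to zero at
    ``support_mm`` beyond the GTV surface.
    """
    if planning_gtv.grid != fraction_gtv.grid:
        raise ValueError("masks must share a grid")
    if support_mm <= 0:
        raise ValueError("support_mm must be positive")
    v_plan = planning_gtv.voxel_count
    v_frac = fraction_gtv.voxel_count
    if v_plan == 0:
        raise ValueError("planning GTV is empty")
    s = (v_frac / v_plan) ** (1.0 / 3.0)
    if s <= 0:
        raise ValueError(f"contraction scale must be positive, got {s}")

    grid = planning_gtv.grid
    if s == 1.0:
        return identity_dvf(grid)

    c = planning_gtv.centroid_mm()
    dist_out = ndimage.distance_transform_edt(
        ~planning_gtv.values, sampling=grid.spacing
    )
    w = np.where(
        dist_out >= support_mm,
        0.0,
        0.5 * (1.0 + np.cos(np.pi * dist_out / support_mm)),
    )
    x, y, z = grid.coords()
    u = np.empty(tuple(grid.shape) + (3,), dtype=float)
    u[..., 0] = (s - 1.0) * (x - c[0]) * w
    u[..., 1] = (s - 1.0) * (y - c[1]) * w
    u[..., 2] = (s - 1.0) * (z - c[2]) * w
    return DVF(grid, u)


def warp_mask(mask: Mask, dvf: DVF, threshold: float = 0.5) -> Mask:
    """Pull a fraction-frame mask back onto the planning grid.

    Samples the mask (as a float image) at x + u(x) and thresholds at 0.5,
    i.e. the same resampling used for dose, restricted to binary images.
    """
    if dvf.grid != mask.grid:
        raise ValueError("mask and DVF must share a grid")
    if dvf.is_identity:
        return Mask(mask.grid, mask.values.copy())
    x, y, z = mask.grid.coords()
    pts = np.stack(
        np.broadcast_arrays(
            x + dvf.displacement[..., 0],
            y + dvf.displacement[..., 1],
            z + dvf.displacement[..., 2],
        ),
        axis=-1,
    )
    idx = mask.grid.world_to_index(pts)
    vals = ndimage.map_coordinates(
        mask.values.astype(float), np.moveaxis(idx, -1, 0), order=1, cval=0.0
    )
    return Mask(mask.grid, vals >= threshold)


def invert_dvf(dvf: DVF, iterations: int = 3) -> DVF:
    """Fixed-point approximation of the inverse displacement field.

    Solves x = y − u(x) for each grid point y, so that the returned field v
    satisfies y + v(y) ≈ φ⁻¹(y) − y + y, i.e. v(y) = −u(φ⁻¹(y)).  Adequate for
    the smooth, small-magnitude contraction fields used here.
    """
    if dvf.is_identity:
        return identity_dvf(dvf.grid)
    x, y, z = dvf.grid.coords()
    pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
    inv = -dvf.displacement.copy()
    for _ in range(iterations):
        inv = -dvf.sample_at(pts + inv)
    return DVF(dvf.grid, inv)
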