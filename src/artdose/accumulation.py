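"""Two-step dose accumulation: warp each fraction's dose into the planning
frame via the deformation field, then sum.

Dose is treated as an intensive quantity: warping is pull-back trilinear
resampling (output(x) = fraction dose at x + u(x) + setup shift) with no
Jacobian/energy rescaling.  Samples outside the fraction grid contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .deform import DVF
from .grid import DoseGrid, GridSpec

__all__ = ["WarpedDoseSeries", "warp_dose", "accumulate_course"]


@dataclass
class WarpedDoseSeries:
    """Per-fraction doses already projected onto one planning grid."""

    grid: GridSpec
    doses: list[DoseGrid] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def append(self, dose: DoseGrid, **prov) -> None:
        if dose.grid != self.grid:
            raise ValueError("warped dose must live on the planning grid")
        self.doses.append(dose)
        self.provenance.append(prov)

    def total(self) -> DoseGrid:
        out = np.zeros(self.grid.shape)
        for d in self.doses:
            out += d.values
        return DoseGrid(self.grid, out)


def warp_dose(
    fraction_dose: DoseGrid,
    dvf: DVF,
    setup_shift_mm=(0.0, 0.0, 0.0),
) -> DoseGrid:
    """Project a fraction-frame dose onto the planning frame.

    output(x) = trilinear sample of the fraction dose at x + u(x) + shift.
    Being a convex combination, the output never exceeds the input maximum
    and is never negative.
    """
    shift = np.asarray(setup_shift_mm, dtype=float)
    if shift.shape != (3,):
        raise ValueError("setup shift must be a 3-vector (mm)")
    if dvf.grid != fraction_dose.grid:
        raise ValueError("DVF must be defined on the planning grid")
    grid = dvf.grid
    if dvf.is_identity and not shift.any():
        return DoseGrid(grid, fraction_dose.values.copy())
    x, y, z = grid.coords()
    pts = np.stack(
        np.broadcast_arrays(
            x + dvf.displacement[..., 0] + shift[0],
            y + dvf.displacement[..., 1] + shift[1],
            z + dvf.displacement[..., 2] + shift[2],
        ),
        axis=-1,
    )
    idx = grid.world_to_index(pts)
    vals = ndimage.map_coordinates(
        fraction_dose.values, np.moveaxis(idx, -1, 0), order=1, cval=0.0
    )
    return DoseGrid(grid, vals)


def accumulate_course(
    fraction_doses: list[DoseGrid],
    dvfs: list[DVF],
    shifts: list | None = None,
) -> DoseGrid:
    """Voxel-wise sum of per-fraction warped doses (pairwise summation).

    Linear in dose, additive over fraction subsets, and order-independent to
    floating-point pairwise-summation tolerance.
    """
    if shifts is None:
        shifts = [np.zeros(3)] * len(fraction_doses)
    if not (len(fraction_doses) == len(dvfs) == len(shifts)):
        raise ValueError(
            f"length mismatch: {len(fraction_doses)} doses, {len(dvfs)} DVFs, "
            f"{len(shifts)} shifts"
        )
    if not fraction_doses:
        raise ValueError("no fractions to accumulate")
    grid = dvfs[0].grid
    warped = np.stack(
        [warp_dose(d, v, s).values
         for d, v, s in zip(fraction_doses, dvfs, shifts)]
    )
    return DoseGrid(grid, warped.sum(axis=0))
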