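"""Idealized conformal dose model standing in for VMAT inverse planning.

The model produces a uniform prescription dose inside the PTV with a
Gaussian lateral falloff outside (distance measured by a Euclidean distance
transform with physical spacing), a low-dose bath across the body, and zero
dose outside the body.  PTV-mean normalization is exact by construction and
D95(PTV) = 100% of prescription, satisfying the clinical normalization
"PTV mean = prescription with D95 ≥ 95%".  Re-optimization against a
background dose rescales the same shape around the current PTV so that the
accumulated PTV-mean telescopes to the prescription.

This is a deterministic surrogate: it has no fluence or arc geometry, but it
preserves the causal link the adaptive-planning comparison measures — a
smaller PTV means less dose to surrounding normal tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import DoseGrid, Mask
from .phantom import EVAL_LUNG, StructureSet
from .radiobiology import dose_at_volume, volume_at_dose

__all__ = [
    "PlanObjectives",
    "FalloffModel",
    "ConstraintResult",
    "optimize_plan",
    "readapt_plan",
    "check_constraints",
]


@dataclass(frozen=True)
class PlanObjectives:
    """Prescription and organ-at-risk limits for one plan.

    Defaults follow NCCN-style constraints for conventionally fractionated
    lung radiotherapy: cord near-max ≤ 45 Gy, mean lung dose ≤ 20 Gy, lung
    V20Gy ≤ 35%, heart mean ≤ 20 Gy and V50Gy ≤ 25%, esophagus mean ≤ 34 Gy.
    """

    prescription_total_gy: float
    fraction_dose_gy: float = 2.0
    d95_fraction: float = 0.95
    cord_dmax_gy: float = 45.0
    lung_mean_gy: float = 20.0
    lung_v20_pct: float = 35.0
    heart_mean_gy: float = 20.0
    heart_v50_pct: float = 25.0
    esophagus_mean_gy: float = 34.0

    def __post_init__(self) -> None:
        if self.prescription_total_gy <= 0 or self.fraction_dose_gy <= 0:
            raise ValueError("prescription and fraction dose must be positive")
        if not 0 < self.d95_fraction <= 1:
            raise ValueError("d95_fraction must lie in (0, 1]")

    @property
    def n_fractions(self) -> int:
        n = self.prescription_total_gy / self.fraction_dose_gy
        if abs(n - round(n)) > 1e-9:
            raise ValueError("prescription is not an integer number of fractions")
        return int(round(n))


@dataclass(frozen=True)
class FalloffModel:
    """Penumbra surrogate: Gaussian scale (mm) and relative body dose bath."""

    sigma_mm: float = 8.0
    bath_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")
        if not 0 <= self.bath_fraction < 1:
            raise ValueError("bath_fraction must lie in [0, 1)")


@dataclass
class ConstraintResult:
    structure: str
    metric: str
    limit: float
    measured: float
    passed: bool


def _conformal_shape(structures: StructureSet, falloff: FalloffModel) -> np.ndarray:
    """Unit-prescription dose shape: 1 in PTV, Gaussian falloff + bath in body."""
    ptv = structures["PTV"]
    if ptv.voxel_count == 0:
        raise ValueError("PTV is empty")
    body = structures["body"].values
    dist = ndimage.distance_transform_edt(
        ~ptv.values, sampling=ptv.grid.spacing
    )
    shape = np.maximum(
        np.exp(-(dist**2) / (2.0 * falloff.sigma_mm**2)), falloff.bath_fraction
    )
    shape[ptv.values] = 1.0
    shape[~body] = 0.0
    return shape


def optimize_plan(
    structures: StructureSet,
    objectives: PlanObjectives,
    falloff: FalloffModel = FalloffModel(),
    warn_on_violation: bool = True,
) -> DoseGrid:
    """Total-course conformal dose around the current PTV.

    PTV-mean equals the prescription exactly and D95(PTV) = prescription
    (uniform interior).  Constraint violations are reported as warnings —
    phantom geometries may violate limits by construction.
    """
    dose = DoseGrid(
        structures.grid,
        objectives.prescription_total_gy * _conformal_shape(structures, falloff),
    )
    if warn_on_violation:
        for res in check_constraints(dose, structures, objectives):
            if not res.passed:
                warnings.warn(
                    f"constraint violated: {res.structure} {res.metric} = "
                    f"{res.measured:.1f} (limit {res.limit})",
                    stacklevel=2,
                )
    return dose


def readapt_plan(
    structures_now: StructureSet,
    objectives: PlanObjectives,
    background: DoseGrid,
    fractions_delivered: int,
    falloff: FalloffModel = FalloffModel(),
) -> DoseGrid:
    """Per-fraction re-optimized dose given the dose already accumulated.

    The remaining-fraction target is p = (prescription − mean background over
    the current PTV) / remaining fractions; the returned grid is the
    conformal shape around the *current* PTV normalized so its PTV-mean
    equals p.  With static anatomy the accumulated PTV-mean telescopes to
    the prescription exactly.
    """
    n_total = objectives.n_fractions
    if fractions_delivered >= n_total:
        raise ValueError("no fractions remain to re-plan")
    if background.grid != structures_now.grid:
        raise ValueError("background dose and structures are on different grids")
    ptv = structures_now["PTV"]
    bg_mean = float(background.in_mask(ptv).mean())
    total = objectives.prescription_total_gy
    if bg_mean >= total:
        raise ValueError(
            f"background PTV-mean {bg_mean:.2f} Gy already reaches the "
            f"prescription {total} Gy; nothing left to deliver"
        )
    per_fraction = (total - bg_mean) / (n_total - fractions_delivered)
    shape = _conformal_shape(structures_now, falloff)
    return DoseGrid(structures_now.grid, per_fraction * shape)


def check_constraints(
    dose: DoseGrid,
    structures: StructureSet,
    objectives: PlanObjectives,
) -> list[ConstraintResult]:
    """Evaluate each organ-at-risk limit against the given total dose.

    Lung is evaluated as both lungs excluding the GTV; cord maximum uses the
    D2% near-maximum convention.
    """
    if dose.grid != structures.grid:
        raise ValueError("dose and structures are on different grids")
    for needed in ("lung_left", "lung_right", "GTV", "heart", "esophagus",
                   "spinal_cord"):
        if needed not in structures:
            raise KeyError(f"missing structure {needed!r} for constraint check")

    lung = dose.in_mask(structures.eval_lung())
    heart = dose.in_mask(structures["heart"])
    eso = dose.in_mask(structures["esophagus"])
    cord = dose.in_mask(structures["spinal_cord"])

    checks = [
        (EVAL_LUNG, "mean_gy", objectives.lung_mean_gy, float(lung.mean())),
        (EVAL_LUNG, "V20Gy_pct", objectives.lung_v20_pct,
         volume_at_dose(lung, 20.0)),
        ("heart", "mean_gy", objectives.heart_mean_gy, float(heart.mean())),
        ("heart", "V50Gy_pct", objectives.heart_v50_pct,
         volume_at_dose(heart, 50.0)),
        ("esophagus", "mean_gy", objectives.esophagus_mean_gy,
         float(eso.mean())),
        ("spinal_cord", "D2pct_gy", objectives.cord_dmax_gy,
         dose_at_volume(cord, 2.0)),
    ]
    return [
        ConstraintResult(s, m, limit, measured, measured <= limit)
        for s, m, limit, measured in checks
    ]
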