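"""Per-fraction course simulation: tumor regression, deformation and setup error.

The regression model is geometric — a constant fractional volume loss per
treatment fraction — optionally modulated by a weekly shrinkage profile that
reproduces the non-uniform regression dynamics observed clinically (slow
start, maximum in weeks 3–4, slower tail).  Shrinkage is isotropic about the
GTV centroid; organs at risk are displaced passively by the contraction field
but are otherwise rigid.  Weekend gaps are ignored: fraction index equals
treatment day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cohort import WEEKLY_GTV_CHANGE
from .deform import DVF, identity_dvf, make_contraction_dvf
from .grid import GridSpec, Mask
from .phantom import StructureSet, expand_margin

__all__ = [
    "RegressionParams",
    "FractionRecord",
    "Course",
    "regression_factor",
    "simulate_course",
    "estimate_regression_rate",
]

_FRACTIONS_PER_WEEK = 5


@dataclass(frozen=True)
class RegressionParams:
    """Tumor-regression model parameters.

    rate_mean / rate_sd
        Per-fraction fractional volume loss across patients (defaults 1.1%
        ± 0.4%, truncated at zero).
    weekly_profile
        Optional sequence of weekly fractional volume changes (negative =
        shrinkage) distributed geometrically over the 5 fractions of each
        week; per-patient heterogeneity scales the log-profile by the ratio
        of the drawn rate to ``rate_mean``.  ``None`` selects the pure
        geometric model.  The default is the observed weekly pattern.
    prestart_progression_prob / prestart_growth_range
        Between planning CT and first fraction (median interval ~7.5 days)
        a patient may progress: with the given probability the GTV grows by
        a factor drawn uniformly from the given relative range.
    linear
        If True, volume loss is linear relative to the planning volume
        (v_k = v_1·(1 − rate·(k−1))) instead of compounding.
    """

    rate_mean: float = 0.011
    rate_sd: float = 0.004
    weekly_profile: tuple[float, ...] | None = WEEKLY_GTV_CHANGE
    prestart_progression_prob: float = 0.5
    prestart_growth_range: tuple[float, float] = (0.066, 0.121)
    prestart_interval_days: float = 7.5
    linear: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.rate_mean < 1:
            raise ValueError("rate_mean must lie in [0, 1)")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be non-negative")

    def volume_multipliers(self, n_fractions: int, rate: float) -> np.ndarray:
        """Fraction-to-fraction GTV volume ratios v_k / v_{k-1} for k = 2..N."""
        if self.weekly_profile is None:
            if self.linear:
                # constant absolute loss relative to the first-fraction volume
                ks = np.arange(1, n_fractions)
                resid = np.maximum(1.0 - rate * np.arange(n_fractions), 1e-9)
                return resid[1:] / resid[:-1]
            return np.full(n_fractions - 1, 1.0 - rate)
        scale = rate / self.rate_mean if self.rate_mean > 0 else 1.0
        mults = np.empty(n_fractions - 1)
        profile = list(self.weekly_profile)
        for k in range(2, n_fractions + 1):
            week = (k - 1) // _FRACTIONS_PER_WEEK  # 0-based week of fraction k
            delta = profile[min(week, len(profile) - 1)]
            weekly = max(1.0 + delta, 1e-6)
            mults[k - 2] = weekly ** (scale / _FRACTIONS_PER_WEEK)
        return mults


@dataclass
class FractionRecord:
    """Anatomy snapshot for one treatment fraction."""

    index: int  # 1-based
    structures: StructureSet
    dvf_to_planning: DVF  # planning-frame field; x -> x + u(x) in this fraction
    setup_shift_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.setup_shift_mm = np.asarray(self.setup_shift_mm, dtype=float)
        if self.setup_shift_mm.shape != (3,):
            raise ValueError("setup_shift_mm must be a 3-vector")


@dataclass
class Course:
    """Planning anatomy plus the ordered per-fraction records of a treatment."""

    planning: StructureSet
    prescription_total_gy: float
    fraction_dose_gy: float
    fractions: list[FractionRecord]

    def __post_init__(self) -> None:
        n = self.prescription_total_gy / self.fraction_dose_gy
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"prescription {self.prescription_total_gy} Gy is not an integer "
                f"multiple of the fraction dose {self.fraction_dose_gy} Gy"
            )
        if len(self.fractions) != round(n):
            raise ValueError(
                f"expected {round(n)} fraction records, got {len(self.fractions)}"
            )

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)


def regression_factor(rate_per_fraction: float, n_fractions: int) -> float:
    """Residual volume fraction (1 − rate)^n after n fractions of geometric decay."""
    if not 0 <= rate_per_fraction < 1:
        raise ValueError("rate must lie in [0, 1)")
    if n_fractions < 0:
        raise ValueError("n_fractions must be non-negative")
    return float((1.0 - rate_per_fraction) ** n_fractions)


def _signed_distance(mask: Mask) -> np.ndarray:
    """Signed distance (mm) to the mask surface, negative inside.

    The zero level sits midway between inside and outside voxel centers,
    which keeps scaled re-rasterizations volume-accurate to sub-voxel level.
    """
    outside = ndimage.distance_transform_edt(~mask.values,
                                             sampling=mask.grid.spacing)
    inside = ndimage.distance_transform_edt(mask.values,
                                            sampling=mask.grid.spacing)
    return outside - inside


def _scaled_gtv(planning_gtv: Mask, scale: float,
                sdf: np.ndarray | None = None) -> Mask:
    """Isotropic contraction of the planning GTV about its centroid.

    A voxel center y belongs to the scaled mask iff its preimage
    c + (y − c)/s lies inside the planning GTV surface, tested on the
    trilinearly interpolated signed-distance field.
    """
    if scale == 1.0:
        return Mask(planning_gtv.grid, planning_gtv.values.copy())
    grid = planning_gtv.grid
    if sdf is None:
        sdf = _signed_distance(planning_gtv)
    c = planning_gtv.centroid_mm()
    x, y, z = grid.coords()
    pts = np.stack(
        np.broadcast_arrays(
            c[0] + (x - c[0]) / scale,
            c[1] + (y - c[1]) / scale,
            c[2] + (z - c[2]) / scale,
        ),
        axis=-1,
    )
    idx = grid.world_to_index(pts)
    vals = ndimage.map_coordinates(
        sdf, np.moveaxis(idx, -1, 0), order=1, mode="nearest"
    )
    return Mask(grid, vals <= 0.0)


def _displace_mask(mask: Mask, dvf: DVF) -> Mask:
    """Push a planning-frame mask into the fraction frame (first-order inverse).

    For the small, smooth displacements at organ distance a one-step inverse
    (sample at y − u(y)) is sufficient; the GTV itself uses the exact scaling.
    """
    if dvf.is_identity:
        return Mask(mask.grid, mask.values.copy())
    x, y, z = mask.grid.coords()
    pts = np.stack(
        np.broadcast_arrays(
            x - dvf.displacement[..., 0],
            y - dvf.displacement[..., 1],
            z - dvf.displacement[..., 2],
        ),
        axis=-1,
    )
    idx = mask.grid.world_to_index(pts)
    vals = ndimage.map_coordinates(
        mask.values.astype(float), np.moveaxis(idx, -1, 0), order=1, cval=0.0
    )
    return Mask(mask.grid, vals >= 0.5)


def simulate_course(
    planning: StructureSet,
    reg: RegressionParams,
    setup_sd_mm: float,
    prescription_total_gy: float,
    seed: int | np.random.SeedSequence,
    fraction_dose_gy: float = 2.0,
    dvf_support_mm: float = 40.0,
    ctv_margin_mm: float = 6.0,
    ptv_margin_mm: float = 6.0,
    adaptation_interval: int = 5,
) -> Course:
    """Generate the per-fraction anatomy of one patient's treatment course.

    The GTV contracts isotropically about its centroid so that volumes follow
    the regression model; CTV and PTV are re-derived by margin expansion at
    the adaptation fractions (1, 1+interval, ...); organs at risk are
    passively displaced by the contraction field; setup shifts are i.i.d.
    Gaussian per axis.  Fully reproducible from ``seed``.
    """
    n = prescription_total_gy / fraction_dose_gy
    if abs(n - round(n)) > 1e-9:
        raise ValueError("prescription must be an integer number of fractions")
    n = int(round(n))
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    rate = max(float(rng.normal(reg.rate_mean, reg.rate_sd)), 0.0)
    progresses = rng.random() < reg.prestart_progression_prob
    lo, hi = reg.prestart_growth_range
    growth = float(rng.uniform(lo, hi)) if progresses else 0.0
    shifts = rng.normal(0.0, setup_sd_mm, size=(n, 3)) if setup_sd_mm > 0 \
        else np.zeros((n, 3))

    mults = reg.volume_multipliers(n, rate)
    rel = np.empty(n)  # v_k / v_planning
    rel[0] = 1.0 + growth
    for k in range(1, n):
        rel[k] = rel[k - 1] * mults[k - 1]

    gtv0 = planning["GTV"]
    sdf0 = _signed_distance(gtv0)
    body = planning["body"]
    records: list[FractionRecord] = []
    weekly_ctv = weekly_ptv = None
    for k in range(1, n + 1):
        scale = rel[k - 1] ** (1.0 / 3.0)
        gtv_k = _scaled_gtv(gtv0, scale, sdf0)
        if gtv_k.voxel_count < 1:
            raise ValueError(f"GTV collapsed below one voxel at fraction {k}")
        dvf = make_contraction_dvf(gtv0, gtv_k, support_mm=dvf_support_mm)
        # re-derive targets on the adaptation images (fractions 1, I, 2I, ...)
        if k == 1 or k % adaptation_interval == 0:
            weekly_ctv = expand_margin(gtv_k, ctv_margin_mm) & body
            weekly_ptv = expand_margin(weekly_ctv, ptv_margin_mm) & body
        masks = {"GTV": gtv_k, "CTV": weekly_ctv, "PTV": weekly_ptv,
                 "body": Mask(body.grid, body.values.copy())}
        for name in ("lung_left", "lung_right", "heart", "esophagus",
                     "spinal_cord"):
            masks[name] = _displace_mask(planning[name], dvf)
        records.append(
            FractionRecord(k, StructureSet(masks), dvf, shifts[k - 1])
        )
    return Course(planning, float(prescription_total_gy), float(fraction_dose_gy),
                  records)


def estimate_regression_rate(volume_series) -> float:
    """Per-fraction regression rate from a volume series via log-linear fit.

    Least-squares slope of log(volume) against fraction index, returned as
    1 − exp(slope): the constant fractional loss that best explains the
    series under geometric decay.
    """
    v = np.asarray(volume_series, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 volumes")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    k = np.arange(v.size, dtype=float)
    slope = np.polyfit(k, np.log(v), 1)[0]
    return float(1.0 - np.exp(slope))
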