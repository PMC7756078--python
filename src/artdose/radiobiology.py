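"""Plan-evaluation mathematics: DVH statistics, conformity and homogeneity
indices, generalized equivalent uniform dose (gEUD) and the logistic
NTCP/TCP dose-response models.

Conventions
-----------
* D_x% is the minimum dose received by the hottest x% of the structure
  volume, evaluated at the descending rank ceil(x·N/100) — an integer-rank
  convention with no interpolation, exactly testable against brute force.
* V_xGy uses the ≥ convention: boundary voxels count as covered.
* Near-extreme doses follow the ICRU 83 practice: D_2% stands in for the
  maximum; gEUD may winsorize voxel doses to [D_99%, D_1%] to suppress
  single-voxel sensitivity.
* gEUD is the power mean (1/N Σ D_i^a)^(1/a); with equal voxel volumes this
  coincides with the volume-weighted EUD formula.  NTCP/TCP are logistic in
  EUD: 1 / (1 + (D50/EUD)^(4·γ50)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, Mask

__all__ = [
    "NiemierkoParams",
    "DEFAULT_RADIOBIO_PARAMS",
    "DVH",
    "dose_at_volume",
    "volume_at_dose",
    "conformity_index",
    "homogeneity_index",
    "geud",
    "eud_from_dvh",
    "ntcp",
    "tcp",
    "cumulative_dvh",
]


@dataclass(frozen=True)
class NiemierkoParams:
    """Per-structure dose-response parameters.

    a       volume-effect exponent of the gEUD power mean (negative for
            targets: cold spots dominate).
    y50     normalized slope of the dose-response curve at the 50% point.
    d50     TD50 for organs at risk / TCD50 for targets (Gy).
    target  True if the structure is a tumor target (TCP instead of NTCP).
    """

    a: float
    y50: float
    d50: float
    target: bool = False

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("exponent a must be nonzero")
        if self.y50 <= 0 or self.d50 <= 0:
            raise ValueError("y50 and d50 must be positive")


#: Published parameter table (heart, spinal cord, esophagus, lung, targets).
#: Spinal-cord values are literature estimates by analogy to the optic nerve.
DEFAULT_RADIOBIO_PARAMS: dict[str, NiemierkoParams] = {
    "heart": NiemierkoParams(a=3, y50=3, d50=50.0),
    "spinal_cord": NiemierkoParams(a=25, y50=3, d50=65.0),
    "esophagus": NiemierkoParams(a=19, y50=4, d50=68.0),
    "lung": NiemierkoParams(a=1, y50=2, d50=24.5),
    "GTV": NiemierkoParams(a=-10, y50=1.81, d50=51.97, target=True),
    "PTV": NiemierkoParams(a=-10, y50=1.81, d50=51.97, target=True),
}


def _as_doses(doses) -> np.ndarray:
    d = np.asarray(doses, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty structure: no voxel doses")
    return d


def dose_at_volume(doses, x: float) -> float:
    """D_x%: minimum dose to the hottest x% of the structure volume (Gy)."""
    d = _as_doses(doses)
    if not 0 < x <= 100:
        raise ValueError(f"x must lie in (0, 100], got {x}")
    rank = int(np.ceil(x / 100.0 * d.size))  # 1-based descending rank
    rank = max(rank, 1)
    return float(np.sort(d)[::-1][rank - 1])


def volume_at_dose(doses, dose_gy: float) -> float:
    """V_dGy: percent of the structure receiving at least ``dose_gy``."""
    d = _as_doses(doses)
    return float(100.0 * np.count_nonzero(d >= dose_gy) / d.size)


def conformity_index(ptv: Mask, dose: DoseGrid, piv_dose_gy: float) -> float:
    """Overlap-based conformity index |PTV∩PIV|² / (|PTV|·|PIV|).

    PIV is the prescribed isodose volume: voxels with dose ≥ ``piv_dose_gy``.
    Equals 1 iff PIV and PTV coincide, 0 if they are disjoint (or PIV empty).
    """
    if ptv.voxel_count == 0:
        raise ValueError("PTV is empty")
    if piv_dose_gy <= 0:
        raise ValueError("piv_dose_gy must be positive")
    piv = dose.values >= piv_dose_gy
    n_piv = int(piv.sum())
    if n_piv == 0:
        return 0.0
    overlap = int((piv & ptv.values).sum())
    return overlap**2 / (ptv.voxel_count * n_piv)


def homogeneity_index(doses) -> float:
    """HI = D5% / D95% of the target; 1 for a perfectly uniform dose."""
    d5 = dose_at_volume(doses, 5.0)
    d95 = dose_at_volume(doses, 95.0)
    if d95 <= 0:
        raise ValueError("HI undefined: D95% is zero")
    return d5 / d95


def _winsorize_near_extremes(d: np.ndarray) -> np.ndarray:
    d1 = dose_at_volume(d, 1.0)
    d99 = dose_at_volume(d, 99.0)
    return np.clip(d, d99, d1)


def geud(doses, a: float, clip: bool = False) -> float:
    """Generalized equivalent uniform dose: power mean with exponent ``a``.

    With ``clip`` the voxel doses are first winsorized to [D_99%, D_1%]
    (near-extreme convention).  For negative ``a`` a zero post-clip dose
    makes the power mean collapse; this returns 0 with a cold-spot warning.
    """
    if a == 0:
        raise ValueError("exponent a must be nonzero")
    d = _as_doses(doses)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if clip:
        d = _winsorize_near_extremes(d)
    if a < 0 and np.any(d == 0):
        warnings.warn(
            "cold spot: zero dose with negative exponent drives gEUD to 0",
            stacklevel=2,
        )
        return 0.0
    if a == 1:
        return float(d.mean())
    # log-domain power mean for numerical robustness at large |a|
    with np.errstate(divide="ignore"):
        logd = np.log(d, out=np.full_like(d, -np.inf), where=d > 0)
    m = np.max(a * logd)
    if not np.isfinite(m):  # all-zero doses with a > 0
        return 0.0
    return float(np.exp((m + np.log(np.mean(np.exp(a * logd - m)))) / a))


def eud_from_dvh(dose_bins, volume_fractions, a: float) -> float:
    """Volume-weighted EUD (Σ v_i·D_i^a)^(1/a) for an imported differential DVH."""
    if a == 0:
        raise ValueError("exponent a must be nonzero")
    d = np.asarray(dose_bins, dtype=float)
    v = np.asarray(volume_fractions, dtype=float)
    if d.shape != v.shape:
        raise ValueError("dose_bins and volume_fractions must align")
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError("volume fractions must sum to 1")
    return float(np.sum(v * d**a) ** (1.0 / a))


def _logistic_response(eud: float, d50: float, y50: float) -> float:
    if eud < 0 or d50 <= 0 or y50 <= 0:
        raise ValueError("eud must be >= 0 and d50, y50 > 0")
    if eud == 0:
        return 0.0
    return float(1.0 / (1.0 + (d50 / eud) ** (4.0 * y50)))


def ntcp(eud: float, td50: float, y50: float) -> float:
    """Normal-tissue complication probability 1/(1 + (TD50/EUD)^(4·γ50))."""
    return _logistic_response(eud, td50, y50)


def tcp(eud: float, tcd50: float, y50: float) -> float:
    """Tumor control probability 1/(1 + (TCD50/EUD)^(4·γ50))."""
    return _logistic_response(eud, tcd50, y50)


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``volume_pct[i]`` is the percent of the structure receiving at least
    ``dose_gy[i]``; the curve starts at 100% at 0 Gy and is non-increasing.
    """

    structure: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if self.dose_gy.shape != self.volume_pct.shape:
            raise ValueError("dose and volume axes must align")
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose_gy": self.dose_gy, "volume_pct": self.volume_pct}
        )

    def plot(self, ax=None, **kwargs):
        """Draw the cumulative curve on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.dose_gy, self.volume_pct, label=self.structure, **kwargs)
        ax.set_xlabel("dose [Gy]")
        ax.set_ylabel("volume [%]")
        ax.set_ylim(0, 105)
        return ax


def cumulative_dvh(dose: DoseGrid, mask: Mask, bin_width_gy: float = 0.1,
                   structure: str = "") -> DVH:
    """Cumulative ≥-dose DVH sampled on a regular dose grid."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    d = dose.in_mask(mask)
    top = d.max() + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    vol = np.array([100.0 * np.count_nonzero(d >= e) / d.size for e in edges])
    return DVH(structure or "structure", edges, vol)
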