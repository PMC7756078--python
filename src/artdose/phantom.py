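"""Synthetic thorax phantom: body, lungs, heart, esophagus, spinal cord and a
spherical gross tumor volume (GTV) nested in one lung.

The phantom is deliberately schematic — binary masks on a shared grid, no CT
intensities — but its geometry is sized so that default tumors span the
~100–500 cm³ range seen in locally advanced NSCLC, and target volumes follow
the clinical GTV → CTV → PTV margin recipe (6 mm + 6 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import GridSpec, Mask

__all__ = [
    "StructureSet",
    "PhantomSpec",
    "build_phantom",
    "expand_margin",
    "gtv_radius_for_volume",
    "EVAL_LUNG",
]

#: Name of the derived evaluation structure: whole lung excluding the GTV.
EVAL_LUNG = "lung"

_OAR_NAMES = ("lung_left", "lung_right", "heart", "esophagus", "spinal_cord")
_TARGET_NAMES = ("GTV", "CTV", "PTV")


@dataclass
class StructureSet:
    """Named organ/target masks sharing one grid.

    Required names: GTV, CTV, PTV, lung_left, lung_right, heart, esophagus,
    spinal_cord, body.  The evaluation lung (both lungs minus GTV) is derived
    on demand via :meth:`eval_lung`.
    """

    masks: dict[str, Mask] = field(repr=False)

    def __post_init__(self) -> None:
        grids = {m.grid for m in self.masks.values()}
        if len(grids) > 1:
            raise ValueError("all masks of a StructureSet must share one grid")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.masks.values())).grid

    def __getitem__(self, name: str) -> Mask:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"structure {name!r} not present") from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    def eval_lung(self) -> Mask:
        """Whole lung (left ∪ right) excluding the GTV."""
        return (self["lung_left"] | self["lung_right"]) - self["GTV"]

    def with_masks(self, **masks: Mask) -> "StructureSet":
        new = dict(self.masks)
        new.update(masks)
        return StructureSet(new)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry parameters of the synthetic thorax (all lengths in mm).

    The tumor is a sphere centered in one lung; either ``gtv_radius_mm`` or
    ``gtv_volume_cm3`` fixes its size.  Margins follow the clinical recipe:
    CTV = GTV + ``ctv_margin_mm``, PTV = CTV + ``ptv_margin_mm``, both clipped
    to the body envelope.
    """

    gtv_radius_mm: float | None = None
    gtv_volume_cm3: float | None = 229.1
    gtv_side: str = "right"  # which lung hosts the tumor
    ctv_margin_mm: float = 6.0
    ptv_margin_mm: float = 6.0
    body_semiaxes_mm: tuple[float, float] = (118.0, 95.0)  # elliptic cylinder
    lung_semiaxes_mm: tuple[float, float, float] = (52.0, 60.0, 112.0)
    lung_offset_mm: float = 62.0  # lateral lung-center displacement
    heart_center_mm: tuple[float, float, float] = (-20.0, 10.0, -30.0)
    heart_semiaxes_mm: tuple[float, float, float] = (40.0, 35.0, 45.0)
    esophagus_center_xy_mm: tuple[float, float] = (0.0, 30.0)
    esophagus_radius_mm: float = 5.0
    cord_center_xy_mm: tuple[float, float] = (0.0, 88.0)
    cord_radius_mm: float = 6.0

    def resolved_gtv_radius_mm(self) -> float:
        if self.gtv_radius_mm is not None:
            return float(self.gtv_radius_mm)
        if self.gtv_volume_cm3 is None:
            raise ValueError("one of gtv_radius_mm / gtv_volume_cm3 is required")
        return gtv_radius_for_volume(self.gtv_volume_cm3)

    def with_gtv_volume(self, volume_cm3: float) -> "PhantomSpec":
        return replace(self, gtv_radius_mm=None, gtv_volume_cm3=float(volume_cm3))


def gtv_radius_for_volume(volume_cm3: float) -> float:
    """Radius (mm) of a sphere with the given volume (cm³)."""
    if volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def expand_margin(mask: Mask, margin_mm: float) -> Mask:
    """Isotropic margin expansion by Euclidean distance on the voxel grid.

    A voxel belongs to the output iff its center lies within ``margin_mm`` of
    some input voxel center (boundary inclusive; anisotropic spacing
    respected).  Identity for ``margin_mm == 0``.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    if margin_mm == 0 or not mask.values.any():
        return Mask(mask.grid, mask.values.copy())
    dist = ndimage.distance_transform_edt(
        ~mask.values, sampling=mask.grid.spacing
    )
    # closed-set convention: centers at exactly the margin distance included
    return Mask(mask.grid, dist <= margin_mm * (1.0 + 1e-12) + 1e-12)


def _ellipsoid(grid: GridSpec, center, semiaxes) -> np.ndarray:
    x, y, z = grid.coords()
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _vertical_tube(grid: GridSpec, center_xy, radius) -> np.ndarray:
    x, y, _ = grid.coords()
    cx, cy = center_xy
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    return np.broadcast_to(r2 <= radius**2, grid.shape).copy()


def _check_bounds(name: str, lo: np.ndarray, hi: np.ndarray, grid: GridSpec) -> None:
    gmin = np.asarray(grid.origin)
    gmax = gmin + np.asarray(grid.extent_mm)
    if np.any(lo < gmin - 1e-9) or np.any(hi > gmax + 1e-9):
        raise ValueError(
            f"structure {name!r} exceeds the grid bounds "
            f"(extent [{lo}, {hi}] vs grid [{gmin}, {gmax}])"
        )


def build_phantom(spec: PhantomSpec, grid: GridSpec) -> StructureSet:
    """Rasterize the phantom geometry onto ``grid``.

    Returns the full structure set with nested GTV ⊆ CTV ⊆ PTV.  Raises if a
    structure would extend beyond the grid, naming the offender.
    """
    r_gtv = spec.resolved_gtv_radius_mm()
    side = 1.0 if spec.gtv_side == "right" else -1.0
    lung_center_host = np.array([side * spec.lung_offset_mm, 0.0, 0.0])
    gtv_center = lung_center_host

    ax_l = np.asarray(spec.lung_semiaxes_mm)
    if r_gtv > min(ax_l):
        raise ValueError(
            f"GTV radius {r_gtv:.1f} mm does not fit inside the lung "
            f"(semi-axes {spec.lung_semiaxes_mm})"
        )

    bx, by = spec.body_semiaxes_mm
    _check_bounds("body", np.array([-bx, -by, grid.origin[2]]),
                  np.array([bx, by, grid.origin[2] + grid.extent_mm[2]]), grid)
    for name, c, ax in (
        ("lung_right", np.array([spec.lung_offset_mm, 0, 0]), ax_l),
        ("lung_left", np.array([-spec.lung_offset_mm, 0, 0]), ax_l),
        ("heart", np.asarray(spec.heart_center_mm), np.asarray(spec.heart_semiaxes_mm)),
    ):
        _check_bounds(name, c - ax, c + ax, grid)
    margin = spec.ctv_margin_mm + spec.ptv_margin_mm
    _check_bounds("PTV", gtv_center - r_gtv - margin, gtv_center + r_gtv + margin, grid)

    x, y, _z = grid.coords()
    body = np.broadcast_to((x / bx) ** 2 + (y / by) ** 2 <= 1.0, grid.shape).copy()

    masks: dict[str, np.ndarray] = {
        "body": body,
        "lung_right": _ellipsoid(grid, (spec.lung_offset_mm, 0, 0), ax_l),
        "lung_left": _ellipsoid(grid, (-spec.lung_offset_mm, 0, 0), ax_l),
        "heart": _ellipsoid(grid, spec.heart_center_mm, spec.heart_semiaxes_mm),
        "esophagus": _vertical_tube(grid, spec.esophagus_center_xy_mm,
                                    spec.esophagus_radius_mm),
        "spinal_cord": _vertical_tube(grid, spec.cord_center_xy_mm,
                                      spec.cord_radius_mm),
    }
    xg, yg, zg = grid.coords()
    gtv = ((xg - gtv_center[0]) ** 2 + (yg - gtv_center[1]) ** 2
           + (zg - gtv_center[2]) ** 2) <= r_gtv**2
    masks["GTV"] = gtv

    out = {name: Mask(grid, v & body if name != "body" else v)
           for name, v in masks.items()}
    ctv = expand_margin(out["GTV"], spec.ctv_margin_mm) & out["body"]
    ptv = expand_margin(ctv, spec.ptv_margin_mm) & out["body"]
    out["CTV"] = ctv
    out["PTV"] = ptv

    sset = StructureSet(out)
    if (sset["GTV"] & sset["spinal_cord"]).voxel_count:
        raise ValueError("GTV overlaps the spinal cord; adjust the geometry")
    return sset
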