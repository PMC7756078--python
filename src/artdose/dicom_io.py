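"""Optional DICOM import: RT-DOSE grids and RT-STRUCT contours for metric
evaluation on real plans.

RT-DOSE pixel data are scaled by DoseGridScaling; the grid geometry comes
from ImagePositionPatient, PixelSpacing and GridFrameOffsetVector (regular
offsets required).  RT-STRUCT contours are rasterized on the dose grid,
slice by slice, with a voxel-center-inside-polygon test.
"""

from __future__ import annotations

import numpy as np

from .grid import DoseGrid, GridSpec, Mask
from .phantom import StructureSet

__all__ = ["read_rtdose", "read_rtstruct"]


def read_rtdose(path) -> DoseGrid:
    """Load an RT-DOSE file into a planning-frame dose grid (Gy)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(f"{path} is not an RT-DOSE object")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pixel_array is (frames, rows, cols) = (z, y, x)
    values = ds.pixel_array.astype(float) * scaling
    values = np.transpose(values, (2, 1, 0))  # -> (x, y, z)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0]):
        raise ValueError("irregular GridFrameOffsetVector is not supported")
    z_sp = float(dz[0]) if offsets.size > 1 else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = GridSpec(tuple(values.shape), (col_sp, row_sp, z_sp), origin)
    return DoseGrid(grid, values)


def _rasterize_polygon(grid: GridSpec, pts_xy: np.ndarray) -> np.ndarray:
    """Boolean (nx, ny) in-polygon test of voxel centers for one z-slice."""
    from matplotlib.path import Path as MplPath

    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    path = MplPath(pts_xy)
    inside = path.contains_points(
        np.column_stack([xx.ravel(), yy.ravel()]), radius=1e-9
    )
    return inside.reshape(xx.shape)


def read_rtstruct(path, grid: GridSpec, names=None) -> StructureSet:
    """Rasterize RT-STRUCT contours onto ``grid``.

    Each contour's points are assigned to the nearest z-slice; multiple
    contours on one slice XOR (holes supported).  ``names`` optionally
    restricts/renames nothing — it just filters ROIs by name.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ValueError(f"{path} is not an RT-STRUCT object")
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in ds.StructureSetROISequence
    }
    z_coords = grid.axis_coords(2)
    masks = {}
    for contour_set in ds.ROIContourSequence:
        name = roi_names.get(int(contour_set.ReferencedROINumber))
        if name is None or (names is not None and name not in names):
            continue
        vol = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(contour_set, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            zi = int(np.argmin(np.abs(z_coords - pts[:, 2].mean())))
            if abs(z_coords[zi] - pts[:, 2].mean()) > grid.spacing[2]:
                continue  # contour outside the grid
            vol[:, :, zi] ^= _rasterize_polygon(grid, pts[:, :2])
        masks[name] = Mask(grid, vol)
    if not masks:
        raise ValueError("no matching ROIs found in RT-STRUCT")
    return StructureSet(masks)
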