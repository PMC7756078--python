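"""Serialization: NRRD grids/masks/DVFs via SimpleITK, JSON manifests.

Array layout note: internal arrays are indexed (x, y, z); SimpleITK images
index (z, y, x) in their numpy view, so axes are transposed on the way in
and out.  World origin and spacing round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .deform import DVF
from .grid import DoseGrid, GridSpec, Mask
from .phantom import StructureSet

__all__ = [
    "write_nrrd",
    "read_nrrd",
    "write_mask",
    "read_mask",
    "write_dose",
    "read_dose",
    "write_dvf",
    "read_dvf",
    "write_structure_set",
    "read_structure_set",
    "write_manifest",
    "read_manifest",
]


def _to_image(values: np.ndarray, grid: GridSpec) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def write_nrrd(path, values: np.ndarray, grid: GridSpec) -> None:
    sitk.WriteImage(_to_image(values, grid), str(path), useCompression=False)


def read_nrrd(path) -> tuple[np.ndarray, GridSpec]:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    grid = GridSpec(tuple(values.shape), tuple(img.GetSpacing()),
                    tuple(img.GetOrigin()))
    return values, grid


def write_mask(path, mask: Mask) -> None:
    write_nrrd(path, mask.values.astype(np.uint8), mask.grid)


def read_mask(path) -> Mask:
    values, grid = read_nrrd(path)
    return Mask(grid, values > 0)


def write_dose(path, dose: DoseGrid) -> None:
    write_nrrd(path, dose.values.astype(np.float64), dose.grid)


def read_dose(path) -> DoseGrid:
    values, grid = read_nrrd(path)
    return DoseGrid(grid, values)


def write_dvf(path_stem, dvf: DVF) -> list[Path]:
    """One NRRD per displacement component: <stem>_ux/_uy/_uz.nrrd."""
    paths = []
    for k, ax in enumerate("xyz"):
        p = Path(f"{path_stem}_u{ax}.nrrd")
        write_nrrd(p, dvf.displacement[..., k].astype(np.float64), dvf.grid)
        paths.append(p)
    return paths


def read_dvf(path_stem) -> DVF:
    comps = []
    grid = None
    for ax in "xyz":
        values, grid = read_nrrd(f"{path_stem}_u{ax}.nrrd")
        comps.append(values)
    return DVF(grid, np.stack(comps, axis=-1))


def write_structure_set(outdir, structures: StructureSet) -> dict[str, str]:
    """One NRRD per mask; returns name → relative filename."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in structures.names():
        fname = f"{name}.nrrd"
        write_mask(out / fname, structures[name])
        files[name] = fname
    return files


def read_structure_set(indir, names=None) -> StructureSet:
    ind = Path(indir)
    paths = sorted(ind.glob("*.nrrd")) if names is None else \
        [ind / f"{n}.nrrd" for n in names]
    masks = {p.stem: read_mask(p) for p in paths}
    if not masks:
        raise FileNotFoundError(f"no structure NRRDs found in {indir}")
    return StructureSet(masks)


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonify)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
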