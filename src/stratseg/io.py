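"""NIfTI I/O and manifest handling.

Internally grids are (z, y, x); NIfTI stores (x, y, z), so arrays are
transposed on the way in and out and spacing/origin tuples are reversed.
Only diagonal (axis-aligned) affines are produced; reading tolerates any
affine but takes spacing from the voxel zooms and origin from the
translation column.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np

from .core import Grid, Mask, OARRegistry, StructureSet, Volume, build_registry


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    aff = np.eye(4)
    for i in range(3):
        aff[i, i] = spacing_zyx[2 - i]
        aff[i, 3] = origin_zyx[2 - i]
    return aff


def _load_geometry(img) -> Tuple[np.ndarray, Tuple[float, ...], Tuple[float, ...]]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D NIfTI payload, got {data.ndim}D with shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    origin_xyz = img.affine[:3, 3]
    spacing_zyx = tuple(float(z) for z in zooms[::-1])
    origin_zyx = tuple(float(o) for o in origin_xyz[::-1])
    return np.ascontiguousarray(data.T), spacing_zyx, origin_zyx


def read_volume(path: str) -> Volume:
    data, spacing, origin = _load_geometry(nib.load(path))
    return Volume(data.astype(np.float32), spacing, origin)


def write_volume(volume: Volume, path: str) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32).T,
        _affine(volume.spacing, volume.origin),
    )
    nib.save(img, path)


def read_mask(path: str) -> Mask:
    data, spacing, origin = _load_geometry(nib.load(path))
    return Mask((data > 0.5).astype(np.uint8), spacing, origin)


def write_mask(mask: Mask, path: str) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask.data, dtype=np.uint8).T, _affine(mask.spacing, mask.origin)
    )
    nib.save(img, path)


def write_structures(
    structures: StructureSet, out_dir: str, manifest_name: str = "structures.json"
) -> str:
    """One NIfTI per mask plus a JSON manifest mapping names to files."""
    os.makedirs(out_dir, exist_ok=True)
    entries = {}
    for name, mask in structures.masks.items():
        fname = f"{name}.nii.gz"
        write_mask(mask, os.path.join(out_dir, fname))
        entries[name] = fname
    manifest = os.path.join(out_dir, manifest_name)
    with open(manifest, "w") as fh:
        json.dump({"masks": entries}, fh, indent=2, sort_keys=True)
    return manifest


def read_structures(
    manifest_path: str, registry: Optional[OARRegistry] = None
) -> StructureSet:
    """Load a structure set from a manifest; names are canonicalized through
    the registry synonym table. All masks must share one grid."""
    registry = registry or build_registry()
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = os.path.dirname(manifest_path)
    masks: Dict[str, Mask] = {}
    grids: Dict[str, Grid] = {}
    for name, fname in manifest["masks"].items():
        canon = registry.entry(name).name
        mask = read_mask(os.path.join(base, fname))
        masks[canon] = mask
        grids[canon] = mask.grid
    if not masks:
        raise ValueError(f"manifest {manifest_path} lists no masks")
    ref_name = next(iter(grids))
    ref = grids[ref_name]
    offenders = [n for n, g in grids.items() if not g.approx_equal(ref)]
    if offenders:
        raise ValueError(
            f"masks do not share one grid: {offenders} differ from {ref_name!r}"
        )
    return StructureSet(masks, ref)


def read_dose(path: str):
    from .dosimetry import DoseGrid

    data, spacing, origin = _load_geometry(nib.load(path))
    return DoseGrid(data.astype(np.float64), spacing, origin)


def write_dose(dose, path: str) -> None:
    img = nib.Nifti1Image(
        np.asarray(dose.data, dtype=np.float32).T, _affine(dose.spacing, dose.origin)
    )
    nib.save(img, path)
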