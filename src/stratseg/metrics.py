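"""Contouring accuracy metrics: Dice overlap and surface distances in mm.

Surfaces are mask voxels with at least one 6-connected background neighbour
(volume borders count as background). Distances are Euclidean distances
between surface-voxel centres in physical millimetres, honouring anisotropic
spacing. The Hausdorff distance is reported as the true maximum; the 95th
percentile variant is computed alongside it since reporting conventions
differ between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Mask, OARRegistry, StructureSet, require_same_grid

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def dsc(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient 2|A.B| / (|A|+|B|); 1.0 if both are empty."""
    require_same_grid(a, b, "DSC operands")
    na, nb = a.volume_voxels(), b.volume_voxels()
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: Mask) -> np.ndarray:
    """Indices (n, 3) of foreground voxels on the mask surface."""
    fg = mask.data > 0
    interior = ndimage.binary_erosion(fg, structure=_STRUCT_6, border_value=0)
    return np.argwhere(fg & ~interior)


def _directed_distances(
    src: np.ndarray, dst: np.ndarray, spacing: Tuple[float, float, float]
) -> np.ndarray:
    sp = np.asarray(spacing)
    tree = cKDTree(dst * sp)
    d, _ = tree.query(src * sp, k=1)
    return d


def _surface_distance_sets(a: Mask, b: Mask) -> Tuple[np.ndarray, np.ndarray]:
    require_same_grid(a, b, "surface-distance operands")
    if a.is_empty() or b.is_empty():
        raise ValueError("surface distances are undefined for an empty mask")
    sa, sb = surface_voxels(a), surface_voxels(b)
    return (
        _directed_distances(sa, sb, a.spacing),
        _directed_distances(sb, sa, a.spacing),
    )


def hausdorff(a: Mask, b: Mask) -> Tuple[float, float]:
    """(HD, HD95) in mm: the symmetric maximum surface distance and the
    maximum of the two directed 95th percentiles."""
    d_ab, d_ba = _surface_distance_sets(a, b)
    hd = float(max(d_ab.max(), d_ba.max()))
    hd95 = float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    return hd, hd95


def asd(a: Mask, b: Mask) -> float:
    """Average surface distance in mm: mean of the two directed averages."""
    d_ab, d_ba = _surface_distance_sets(a, b)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


@dataclass
class SegMetricsReport:
    """Per-OAR metric rows plus per-stratum and overall means."""

    per_oar: Dict[str, Dict[str, float]] = field(default_factory=dict)
    skipped: List[str] = field(default_factory=list)
    flags: Dict[str, str] = field(default_factory=dict)

    def _mean_over(self, names: List[str], key: str) -> Optional[float]:
        vals = [self.per_oar[n][key] for n in names if n in self.per_oar]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.mean(vals)) if vals else None

    def stratum_means(self, registry: OARRegistry) -> Dict[str, Dict[str, Optional[float]]]:
        out: Dict[str, Dict[str, Optional[float]]] = {}
        for stratum in ("anchor", "mid-level", "small_hard"):
            names = registry.names(stratum)
            out[stratum] = {
                key: self._mean_over(names, key)
                for key in ("dsc", "hd_mm", "hd95_mm", "asd_mm")
            }
        out["all"] = {
            key: self._mean_over(list(self.per_oar), key)
            for key in ("dsc", "hd_mm", "hd95_mm", "asd_mm")
        }
        return out

    def to_table(self):
        import pandas as pd

        rows = [{"oar": n, **vals} for n, vals in self.per_oar.items()]
        return pd.DataFrame(rows)


def evaluate_case(
    pred: StructureSet, ref: StructureSet, registry: OARRegistry
) -> SegMetricsReport:
    """Evaluate every OAR present in both sets; structures absent from either
    set are listed as skipped and excluded from the means (institutional
    protocols annotate variable OAR subsets)."""
    report = SegMetricsReport()
    ref_canon = {registry.entry(n).name: n for n in ref.names()}
    pred_canon = {registry.entry(n).name: n for n in pred.names()}
    all_names = set(ref_canon) | set(pred_canon)
    common = sorted(set(ref_canon) & set(pred_canon))
    if not common:
        raise ValueError("no common OAR names between prediction and reference")
    report.skipped = sorted(all_names - set(common))

    for canon in common:
        p, r = pred[pred_canon[canon]], ref[ref_canon[canon]]
        row: Dict[str, float] = {"dsc": dsc(p, r)}
        if p.is_empty() or r.is_empty():
            row.update({"hd_mm": np.nan, "hd95_mm": np.nan, "asd_mm": np.nan})
            report.flags[canon] = "empty mask: surface distances undefined"
            if p.is_empty() and r.is_empty():
                report.flags[canon] = "both masks empty: DSC defined as 1.0"
        else:
            hd, hd95 = hausdorff(p, r)
            row.update({"hd_mm": hd, "hd95_mm": hd95, "asd_mm": asd(p, r)})
        report.per_oar[canon] = row
    return report
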