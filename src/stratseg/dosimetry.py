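"""Dose metrics over contours and contour-substitution dose-difference statistics.

The dose grid may be coarser than the image grid (planning systems commonly
store dose at 2-4 mm voxels), so masks are transferred onto the dose grid by
nearest-neighbour lookup in physical coordinates before any dose statistic
is computed.

Two evaluation modes quantify the dosimetric impact of swapping a reference
contour set for a substitute one:

* direct — the planned dose grid is kept fixed and only the contours change:
  ``diff = (metric(substitute, dose_ref) - metric(ref, dose_ref)) / metric(ref, dose_ref) * 100``
* clinical — a dose grid replanned around the substitute contours is supplied,
  and both terms are evaluated on that substitute grid, the reference contours
  being overlaid on it:
  ``diff = (metric(substitute, dose_sub) - metric(ref, dose_sub)) / metric(ref, dose_sub) * 100``

Percentages are signed; summary rows report signed and absolute means plus
the fraction of structures exceeding 10% and 30% absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .core import Grid, Mask, StructureSet


@dataclass
class DoseGrid:
    """3D dose values in Gy on a (possibly coarse) grid."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"dose grid must be 3D, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("doses must be nonnegative")
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(s) for s in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)


def resample_mask_to_dose(mask: Mask, dose: DoseGrid) -> np.ndarray:
    """Nearest-neighbour transfer of a binary mask onto the dose grid.

    Each dose voxel centre is mapped to the nearest image voxel in physical
    coordinates; out-of-bounds dose voxels are background.
    """
    if mask.grid.approx_equal(dose.grid):
        return mask.data.astype(bool)
    shape = dose.data.shape
    out = np.zeros(shape, dtype=bool)
    axes_idx = []
    inside = None
    for ax in range(3):
        centers_mm = (
            np.arange(shape[ax]) * dose.spacing[ax] + dose.origin[ax]
        )
        idx = np.rint((centers_mm - mask.origin[ax]) / mask.spacing[ax]).astype(int)
        ok = (idx >= 0) & (idx < mask.data.shape[ax])
        axes_idx.append(np.clip(idx, 0, mask.data.shape[ax] - 1))
        in_ax = ok.reshape([-1 if a == ax else 1 for a in range(3)])
        inside = in_ax if inside is None else (inside & in_ax)
    out = mask.data[np.ix_(axes_idx[0], axes_idx[1], axes_idx[2])].astype(bool)
    return out & inside


def _mask_on_dose(mask: Mask, dose: DoseGrid, name: str = "mask") -> np.ndarray:
    sel = resample_mask_to_dose(mask, dose)
    if not sel.any():
        raise ValueError(f"{name}: mask is empty after resampling to the dose grid")
    return sel


def mean_dose(mask: Mask, dose: DoseGrid, name: str = "mask") -> float:
    """Mean dose (Gy) over the dose-grid voxels covered by the mask."""
    sel = _mask_on_dose(mask, dose, name)
    return float(dose.data[sel].mean())


def max_dose(mask: Mask, dose: DoseGrid, name: str = "mask") -> float:
    """Maximum voxel dose (Gy) inside the mask on the dose grid."""
    sel = _mask_on_dose(mask, dose, name)
    return float(dose.data[sel].max())


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of structure volume
    receiving at least each dose level."""

    dose_edges_gy: np.ndarray
    fraction_volume: np.ndarray

    def value_at(self, dose_gy: float) -> float:
        i = int(np.searchsorted(self.dose_edges_gy, dose_gy, side="right")) - 1
        i = max(0, min(i, len(self.fraction_volume) - 1))
        return float(self.fraction_volume[i])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose_gy": self.dose_edges_gy, "fraction_volume": self.fraction_volume}
        )


def dvh(mask: Mask, dose: DoseGrid, bin_width_gy: float = 0.5) -> DVHCurve:
    """Cumulative DVH sampled at bin edges 0, w, 2w, ... beyond the max dose."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    sel = _mask_on_dose(mask, dose)
    doses = dose.data[sel]
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = np.array([(doses >= e).mean() for e in edges])
    return DVHCurve(edges, frac)


@dataclass
class DoseDiffReport:
    """Per-OAR signed percentage differences in mean and maximum dose."""

    mode: str  # "direct" or "clinical"
    substitute_name: str
    per_oar: Dict[str, Dict[str, float]] = field(default_factory=dict)
    skipped: Dict[str, str] = field(default_factory=dict)

    def summary(self) -> Dict[str, float]:
        if not self.per_oar:
            return {}
        mean_diffs = np.array([v["diff_mean_pct"] for v in self.per_oar.values()])
        max_diffs = np.array([v["diff_max_pct"] for v in self.per_oar.values()])
        return {
            "n_oars": len(self.per_oar),
            "signed_mean_of_diff_mean_pct": float(mean_diffs.mean()),
            "signed_mean_of_diff_max_pct": float(max_diffs.mean()),
            "abs_mean_of_diff_mean_pct": float(np.abs(mean_diffs).mean()),
            "abs_mean_of_diff_max_pct": float(np.abs(max_diffs).mean()),
            "frac_mean_diff_gt_10pct": float((np.abs(mean_diffs) > 10).mean()),
            "frac_mean_diff_gt_30pct": float((np.abs(mean_diffs) > 30).mean()),
            "frac_max_diff_gt_10pct": float((np.abs(max_diffs) > 10).mean()),
            "frac_max_diff_gt_30pct": float((np.abs(max_diffs) > 30).mean()),
        }

    def to_table(self):
        import pandas as pd

        rows = [
            {"oar": name, "mode": self.mode, "substitute": self.substitute_name, **vals}
            for name, vals in self.per_oar.items()
        ]
        return pd.DataFrame(rows)


def _pct_diffs(
    ref_mask: Mask, sub_mask: Mask, dose: DoseGrid, name: str
) -> Dict[str, float]:
    ref_mean = mean_dose(ref_mask, dose, name=f"reference {name}")
    ref_max = max_dose(ref_mask, dose, name=f"reference {name}")
    if ref_mean == 0 or ref_max == 0:
        raise ZeroDivisionError(
            f"reference dose metric is zero for {name!r}; percentage difference undefined"
        )
    sub_mean = mean_dose(sub_mask, dose, name=f"substitute {name}")
    sub_max = max_dose(sub_mask, dose, name=f"substitute {name}")
    return {
        "diff_mean_pct": (sub_mean - ref_mean) / ref_mean * 100.0,
        "diff_max_pct": (sub_max - ref_max) / ref_max * 100.0,
        "ref_mean_gy": ref_mean,
        "ref_max_gy": ref_max,
        "sub_mean_gy": sub_mean,
        "sub_max_gy": sub_max,
    }


def diff_direct(
    ref: StructureSet,
    substitute: StructureSet,
    dose_ref: DoseGrid,
    substitute_name: str = "substitute",
) -> DoseDiffReport:
    """Direct dosimetric differences: planned dose grid fixed, contours swapped."""
    report = DoseDiffReport(mode="direct", substitute_name=substitute_name)
    common = [n for n in ref.names() if n in substitute]
    if not common:
        raise ValueError("no common OAR names between reference and substitute sets")
    for name in common:
        try:
            report.per_oar[name] = _pct_diffs(ref[name], substitute[name], dose_ref, name)
        except ValueError as exc:
            report.skipped[name] = str(exc)
    return report


def diff_clinical(
    ref: StructureSet,
    substitute: StructureSet,
    dose_substitute: DoseGrid,
    substitute_name: str = "substitute",
) -> DoseDiffReport:
    """Clinical dosimetric differences: both terms evaluated on the dose grid
    replanned around the substitute contours, reference contours overlaid."""
    report = DoseDiffReport(mode="clinical", substitute_name=substitute_name)
    common = [n for n in ref.names() if n in substitute]
    if not common:
        raise ValueError("no common OAR names between reference and substitute sets")
    for name in common:
        try:
            report.per_oar[name] = _pct_diffs(
                ref[name], substitute[name], dose_substitute, name
            )
        except ValueError as exc:
            report.skipped[name] = str(exc)
    return report
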