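"""Detection geometry: Gaussian heatmap targets, peak extraction, VOI crops.

Small low-contrast organs are found by regressing one heatmap per class —
a 3D Gaussian bump at the organ centre in physical coordinates — then
cropping a volume of interest (VOI) of three times the class's maximum
extent around the peak for zoom-in segmentation. Crops are half-open
windows ``[start, start + size)``; when a window would cross the volume
border it is shifted inward (size preserved) and only truncated when an
axis is smaller than the window itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import Grid, Mask, OAREntry, Volume


def gaussian_target(
    center: Tuple[int, int, int], sigma_mm: float, grid: Grid
) -> np.ndarray:
    """Heatmap h(v) = exp(-||p(v) - p(center)||^2 / (2 sigma^2)) in mm.

    The peak value is exactly 1 at the centre voxel; anisotropic spacing is
    honoured through physical distances.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    center = tuple(int(c) for c in center)
    for ax, c in enumerate(center):
        if not (0 <= c < grid.shape[ax]):
            raise ValueError(f"center {center} out of bounds for grid {grid.shape}")
    axes = [
        ((np.arange(grid.shape[ax]) - center[ax]) * grid.spacing[ax]) ** 2
        for ax in range(3)
    ]
    d2 = (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )
    return np.exp(-d2 / (2.0 * sigma_mm**2)).astype(np.float32)


def extract_peak(heatmap: np.ndarray) -> Tuple[int, int, int]:
    """Voxel index of the global maximum; ties resolve to the lexicographically
    smallest (z, y, x). An all-constant map warns and returns (0, 0, 0)."""
    h = np.asarray(heatmap)
    if h.size == 0:
        raise ValueError("cannot extract a peak from an empty heatmap")
    if np.all(h == h.flat[0]):
        warnings.warn("heatmap is constant; returning (0, 0, 0)", stacklevel=2)
    return tuple(int(i) for i in np.unravel_index(int(np.argmax(h)), h.shape))


@dataclass
class VOICrop:
    """A cropped sub-volume with enough geometry to paste results back."""

    start: Tuple[int, int, int]
    size: Tuple[int, int, int]
    source_grid: Grid
    volume: Volume

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(
            slice(s, s + n) for s, n in zip(self.start, self.size)
        )


def crop_voi(x: Volume, center: Tuple[int, int, int], entry: OAREntry) -> VOICrop:
    """Crop three times the class's maximum extent around a detected centre.

    Per axis the window size is ``round(3 * max_extent_mm / spacing)`` voxels
    (at least 1), clamped to the volume by shifting the window inward; the
    size is only reduced when the whole axis is shorter than the window.
    """
    if entry.max_extent_mm is None:
        raise ValueError(
            f"OAR {entry.name!r} has no max_extent_mm; measure it from training "
            "labels or set it in the registry before cropping"
        )
    shape = x.data.shape
    center = tuple(int(c) for c in center)
    for ax, c in enumerate(center):
        if not (0 <= c < shape[ax]):
            raise ValueError(f"center {center} out of bounds for volume {shape}")
    size = []
    start = []
    for ax in range(3):
        n = max(1, int(round(3.0 * entry.max_extent_mm[ax] / x.spacing[ax])))
        n = min(n, shape[ax])
        s = center[ax] - n // 2
        s = min(max(s, 0), shape[ax] - n)
        size.append(n)
        start.append(s)
    sl = tuple(slice(s, s + n) for s, n in zip(start, size))
    sub = Volume(
        x.data[sl].copy(),
        x.spacing,
        tuple(o + s * sp for o, s, sp in zip(x.origin, start, x.spacing)),
    )
    return VOICrop(tuple(start), tuple(size), x.grid, sub)


def paste_voi(
    full_grid: Grid,
    voi_probs: np.ndarray,
    crop: VOICrop,
    class_index: int = 1,
) -> Mask:
    """Place the argmax of VOI class probabilities into an otherwise-empty
    full-size mask: voxels outside the crop window are always zero."""
    if not crop.source_grid.approx_equal(full_grid):
        raise ValueError("crop source geometry does not match the full grid")
    if tuple(voi_probs.shape[1:]) != tuple(crop.size):
        raise ValueError(
            f"VOI prediction shape {voi_probs.shape[1:]} does not match crop size {crop.size}"
        )
    labels = np.argmax(voi_probs, axis=0)
    out = np.zeros(full_grid.shape, dtype=np.uint8)
    out[crop.slices()] = (labels == class_index).astype(np.uint8)
    return Mask(out, full_grid.spacing, full_grid.origin)
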