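"""Synthetic phantom generation.

Produces desk-scale 3D volumes containing non-overlapping ellipsoidal
structures in three difficulty strata — large high-contrast (anchor-like),
mid-size moderate-contrast (mid-level-like), and tiny low-contrast
(small-and-hard-like) — together with analytic Gaussian dose fields and
smoothly perturbed contours emulating inter-reader variation. Everything is
a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    ANCHOR,
    MID_LEVEL,
    SMALL_HARD,
    Mask,
    OARRegistry,
    StructureSet,
    Volume,
    build_registry,
)
from .dosimetry import DoseGrid


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a structure without overlap."""


@dataclass(frozen=True)
class StructureSpec:
    """Per-stratum generation parameters: how many ellipsoids, their per-axis
    radius range (mm) and additive intensity contrast over background."""

    count: int
    radius_mm: Tuple[float, float]
    contrast: float
    contrast_spread: float = 0.8

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        lo, hi = self.radius_mm
        if not (0 < lo <= hi):
            raise ValueError(f"bad radius range {self.radius_mm}")
        if not (0 <= self.contrast_spread < 1):
            raise ValueError("contrast_spread must be in [0, 1)")

    def instance_contrast(self, i: int) -> float:
        """Deterministic per-instance contrast, evenly spread over
        ``contrast * (1 +/- contrast_spread / 2)`` and centred on ``contrast``.

        Instances within a stratum would otherwise be indistinguishable in
        appearance, leaving their class identity purely positional."""
        if self.count <= 1:
            return self.contrast
        frac = i / (self.count - 1) - 0.5
        return self.contrast * (1.0 + self.contrast_spread * frac)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic case.

    Defaults give a 64x96x96 voxel volume at 1.5 mm isotropic spacing
    carrying the full 42-structure registry (9 anchor, 19 mid-level, 14
    small-hard) with anchor > mid-level > small-hard contrast ordering
    (300/100/30 intensity units over background, each spread +/-40% across a
    stratum's instances the way distinct organs differ in HU) and Gaussian
    image noise of std 10.
    """

    shape: Tuple[int, int, int] = (64, 96, 96)
    spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5)
    anchor: StructureSpec = field(default_factory=lambda: StructureSpec(9, (9.0, 14.0), 300.0))
    mid: StructureSpec = field(default_factory=lambda: StructureSpec(19, (5.0, 8.0), 100.0))
    small_hard: StructureSpec = field(default_factory=lambda: StructureSpec(14, (2.5, 4.5), 30.0))
    background: float = 0.0
    noise_std: float = 10.0
    seed: int = 0

    def spec_for(self, stratum: str) -> StructureSpec:
        return {ANCHOR: self.anchor, MID_LEVEL: self.mid, SMALL_HARD: self.small_hard}[stratum]


def _ellipsoid_mask(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_vox: np.ndarray,
    radii_mm: np.ndarray,
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    d = np.zeros(shape, dtype=np.float64)
    for ax, grid in enumerate((zz, yy, xx)):
        d += ((grid - center_vox[ax]) * spacing[ax] / radii_mm[ax]) ** 2
    return d <= 1.0


def generate_phantom(
    config: PhantomConfig, registry: Optional[OARRegistry] = None
) -> Tuple[Volume, StructureSet]:
    """Generate one phantom volume and its reference structure set.

    Structures are named after registry entries of the matching stratum, in
    registry order. Overlap is forbidden: placement uses rejection sampling
    with at most 1000 attempts per structure. Identical config (including
    seed) yields bit-identical output.
    """
    registry = registry or build_registry()
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape)
    spacing = tuple(float(s) for s in config.spacing)

    occupied = np.zeros(shape, dtype=bool)
    masks = {}
    intensity = np.full(shape, config.background, dtype=np.float64)

    for stratum in (ANCHOR, MID_LEVEL, SMALL_HARD):
        spec = config.spec_for(stratum)
        names = registry.names(stratum)
        if spec.count > len(names):
            raise ValueError(
                f"cannot generate {spec.count} {stratum} structures: registry has "
                f"only {len(names)} names"
            )
        for i in range(spec.count):
            placed = False
            for _attempt in range(1000):
                radii = rng.uniform(spec.radius_mm[0], spec.radius_mm[1], size=3)
                rad_vox = radii / np.asarray(spacing)
                # keep structures strictly inside the volume (>=1 voxel margin)
                lo = np.ceil(rad_vox) + 1
                hi = np.asarray(shape) - np.ceil(rad_vox) - 2
                if np.any(hi < lo):
                    continue
                center = rng.uniform(lo, hi)
                mask = _ellipsoid_mask(shape, spacing, center, radii)
                if not mask.any():
                    continue
                grown = ndimage.binary_dilation(mask)
                if not (grown & occupied).any():
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place {stratum} structure #{i} without overlap "
                    "after 1000 attempts; reduce counts or radii"
                )
            occupied |= mask
            intensity += spec.instance_contrast(i) * mask
            masks[names[i]] = Mask(mask.astype(np.uint8), spacing)

    if config.noise_std > 0:
        intensity = intensity + rng.normal(0.0, config.noise_std, size=shape)
    volume = Volume(intensity.astype(np.float32), spacing)
    return volume, StructureSet(masks, volume.grid)


@dataclass(frozen=True)
class DoseFieldConfig:
    """Analytic stand-in for a planned dose distribution: a Gaussian falloff
    around the target centroid, in Gy."""

    prescription_dose: float = 70.0
    falloff_sigma_mm: float = 20.0
    background_dose: float = 0.0
    grid_spacing_mm: Optional[Tuple[float, float, float]] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if not (self.prescription_dose > self.background_dose >= 0):
            raise ValueError("need prescription_dose > background_dose >= 0")
        if self.falloff_sigma_mm <= 0:
            raise ValueError("falloff_sigma_mm must be > 0")


def generate_dose_grid(target: Mask, config: DoseFieldConfig) -> DoseGrid:
    """Dose(v) = background + (prescription - background) * exp(-d(v)^2 / 2 sigma^2)
    with d the physical distance from the voxel centre to the target centroid.

    The dose grid covers the target mask's physical extent, by default at a
    coarser spacing (planning systems store dose on 2-4 mm grids); pass
    ``grid_spacing_mm=None`` to reuse the mask grid.
    """
    if target.is_empty():
        raise ValueError("dose field requires a nonempty target mask")
    tgt_idx = np.argwhere(target.data > 0)
    centroid_mm = target.grid.voxel_centers_mm(tgt_idx.mean(axis=0))

    spacing = config.grid_spacing_mm or target.spacing
    spacing = tuple(float(s) for s in spacing)
    extent_mm = np.asarray(target.data.shape) * np.asarray(target.spacing)
    shape = tuple(int(max(1, np.ceil(e / s))) for e, s in zip(extent_mm, spacing))

    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    coords = np.stack([zz, yy, xx], axis=-1) * np.asarray(spacing) + np.asarray(
        target.origin
    )
    d2 = ((coords - centroid_mm) ** 2).sum(axis=-1)
    dose = config.background_dose + (
        config.prescription_dose - config.background_dose
    ) * np.exp(-d2 / (2.0 * config.falloff_sigma_mm**2))
    return DoseGrid(dose.astype(np.float64), spacing, target.origin)


def perturb_mask(
    mask: Mask, magnitude_mm: float, seed: int, smooth_mm: float = 8.0
) -> Mask:
    """Emulate an independent reader's contour of the same structure.

    Applies a smooth random displacement field plus a random morphological
    offset (dilation or erosion), together sized so the expected boundary
    displacement is ``magnitude_mm``. Magnitude 0 returns the input
    unchanged; output is deterministic given the seed.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if magnitude_mm == 0:
        return Mask(mask.data.copy(), mask.spacing, mask.origin)

    rng = np.random.default_rng(seed)
    shape = mask.data.shape
    spacing = np.asarray(mask.spacing)

    # Half the displacement budget: uniform boundary offset via the exact
    # Euclidean distance transform (dilation for +delta, erosion for -delta).
    delta_mm = rng.choice([-1.0, 1.0]) * 0.5 * magnitude_mm
    if delta_mm >= 0:
        dist = ndimage.distance_transform_edt(mask.data == 0, sampling=mask.spacing)
        offset = (mask.data > 0) | (dist <= delta_mm)
    else:
        dist = ndimage.distance_transform_edt(mask.data > 0, sampling=mask.spacing)
        offset = dist > -delta_mm

    # Other half: smooth random deformation, normalized so the mean
    # displacement magnitude is 0.5 * magnitude_mm.
    sigma_vox = smooth_mm / spacing
    field_mm = np.empty((3,) + shape)
    for ax in range(3):
        noise = rng.standard_normal(shape)
        field_mm[ax] = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    norms = np.sqrt((field_mm**2).sum(axis=0))
    mean_norm = norms.mean()
    if mean_norm > 0:
        field_mm *= (0.5 * magnitude_mm) / mean_norm

    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    sample_at = [
        g - field_mm[ax] / spacing[ax] for ax, g in enumerate((zz, yy, xx))
    ]
    warped = ndimage.map_coordinates(
        offset.astype(np.float32), sample_at, order=1, mode="nearest"
    )
    return Mask((warped >= 0.5).astype(np.uint8), mask.spacing, mask.origin)
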