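"""Core domain types: volumes, masks, structure sets, and the OAR registry.

All grids use (z, y, x) axis order with 0-based voxel indices. ``spacing``
and ``origin`` are physical millimetres in the same (z, y, x) order. Crop
intervals are half-open ``[start, start + size)`` throughout the package.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

ANCHOR = "anchor"
MID_LEVEL = "mid-level"
SMALL_HARD = "small_hard"
STRATA = (ANCHOR, MID_LEVEL, SMALL_HARD)


class UnknownOARError(KeyError):
    """Raised when a structure name cannot be resolved against the registry."""


class GeometryError(ValueError):
    """Raised when two grids that must share a geometry do not."""


@dataclass(frozen=True)
class Grid:
    """Voxel grid geometry: shape in voxels, spacing and origin in mm (z, y, x)."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive extents, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be 3 positive values, got {self.spacing}")

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices, shape (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def approx_equal(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _check_3d(data: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(f"{what} must be 3D, got {arr.ndim}D with shape {arr.shape}")
    if any(s <= 0 for s in arr.shape):
        raise ValueError(f"{what} must have positive extents, got shape {arr.shape}")
    return arr


@dataclass
class Volume:
    """A 3D scalar image (CT-like HU or unitless phantom intensity)."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = _check_3d(self.data, "Volume data").astype(np.float32, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(s) for s in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)


@dataclass
class Mask:
    """A binary 3D label grid aligned to a :class:`Volume` geometry."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = _check_3d(self.data, "Mask data")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(s) for s in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def volume_voxels(self) -> int:
        return int(self.data.sum())

    def centroid_voxel(self) -> Tuple[int, int, int]:
        """Centroid of foreground voxels, rounded to the nearest voxel index."""
        if self.is_empty():
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.data > 0)
        c = idx.mean(axis=0)
        return tuple(int(round(v)) for v in c)

    def bbox_extent_mm(self) -> Tuple[float, float, float]:
        """Per-axis physical size of the tight bounding box (mm)."""
        if self.is_empty():
            raise ValueError("bounding box of an empty mask is undefined")
        idx = np.argwhere(self.data > 0)
        span = idx.max(axis=0) - idx.min(axis=0) + 1
        return tuple(float(s * sp) for s, sp in zip(span, self.spacing))


def require_same_grid(a, b, what: str = "operands") -> None:
    if not a.grid.approx_equal(b.grid):
        raise GeometryError(
            f"{what} must share one grid: {a.grid.shape}/{a.grid.spacing} vs "
            f"{b.grid.shape}/{b.grid.spacing}"
        )


@dataclass
class StructureSet:
    """Named per-OAR binary masks on one shared grid."""

    masks: Dict[str, Mask]
    grid: Grid

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            if not mask.grid.approx_equal(self.grid):
                raise GeometryError(f"mask '{name}' does not match the structure-set grid")

    @classmethod
    def from_masks(cls, masks: Dict[str, Mask]) -> "StructureSet":
        if not masks:
            raise ValueError("cannot build a StructureSet from zero masks")
        first = next(iter(masks.values()))
        return cls(masks=dict(masks), grid=first.grid)

    def names(self) -> List[str]:
        return list(self.masks)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> Mask:
        return self.masks[name]

    def __len__(self) -> int:
        return len(self.masks)


@dataclass(frozen=True)
class OAREntry:
    """One organ-at-risk class: canonical name, difficulty stratum, laterality.

    ``max_extent_mm`` is the per-axis maximum bounding-box size of the class,
    used to size detection crops (three times this extent). It is unset until
    measured from reference labels or supplied by configuration.
    """

    name: str
    stratum: str
    laterality: str = "none"
    max_extent_mm: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}, got {self.stratum!r}")
        if self.laterality not in ("left", "right", "none"):
            raise ValueError(f"bad laterality {self.laterality!r}")
        if self.max_extent_mm is not None:
            ext = tuple(float(v) for v in self.max_extent_mm)
            if len(ext) != 3 or any(v <= 0 for v in ext):
                raise ValueError(f"max_extent_mm must be 3 positive values, got {ext}")
            object.__setattr__(self, "max_extent_mm", ext)


# The registry's synonym table maps common clinical spellings (e.g. "TMJ_Lt",
# "SMG_Rt", "OpticChiasm") onto the canonical lowercase snake_case names.
_SYNONYMS = {
    "brainstem": "brainstem",
    "brain_stem": "brainstem",
    "gsl": "glottic_supraglottic_larynx",
    "glottic_and_supraglottic_larynx": "glottic_supraglottic_larynx",
    "smg_left": "submandibular_left",
    "smg_right": "submandibular_right",
    "submandibular_gland_left": "submandibular_left",
    "submandibular_gland_right": "submandibular_right",
    "temp_lobe_left": "temporal_lobe_left",
    "temp_lobe_right": "temporal_lobe_right",
    "templobe_left": "temporal_lobe_left",
    "templobe_right": "temporal_lobe_right",
    "basalganglia_left": "basal_ganglia_left",
    "basalganglia_right": "basal_ganglia_right",
    "brachial_left": "brachial_plexus_left",
    "brachial_right": "brachial_plexus_right",
    "const_inf": "constrictor_inferior",
    "const_mid": "constrictor_middle",
    "const_sup": "constrictor_superior",
    "opticchiasm": "optic_chiasm",
    "opticnerve_left": "optic_nerve_left",
    "opticnerve_right": "optic_nerve_right",
    "innerear_left": "inner_ear_left",
    "innerear_right": "inner_ear_right",
    "lacrimalgland_left": "lacrimal_gland_left",
    "lacrimalgland_right": "lacrimal_gland_right",
    "pinealgland": "pineal_gland",
    "oralcavity": "oral_cavity",
    "spinalcord": "spinal_cord",
    "glottic_area": "glottic_area",
    "tmjoint_left": "tmj_left",
    "tmjoint_right": "tmj_right",
}

_SUFFIXES = (("_lt", "_left"), ("_rt", "_right"), ("_l", "_left"), ("_r", "_right"))


def canonicalize_name(name: str) -> str:
    """Normalize a structure name to its canonical form (no registry lookup)."""
    s = name.strip().lower().replace("-", "_").replace(" ", "_")
    for suf, repl in _SUFFIXES:
        if s.endswith(suf):
            s = s[: -len(suf)] + repl
            break
    return _SYNONYMS.get(s, s)


@dataclass
class OARRegistry:
    """Ordered collection of OAR entries with per-stratum class indices.

    Class index 0 is reserved for background in every stratum; foreground
    classes are numbered 1..C in registry order within each stratum.
    """

    entries: List[OAREntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("registry names must be unique")
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[OAREntry]:
        return iter(self.entries)

    def names(self, stratum: Optional[str] = None) -> List[str]:
        if stratum is None:
            return [e.name for e in self.entries]
        return [e.name for e in self.entries if e.stratum == stratum]

    def entry(self, name: str) -> OAREntry:
        canon = canonicalize_name(name)
        if canon not in self._by_name:
            near = difflib.get_close_matches(canon, self._by_name, n=3)
            raise UnknownOARError(
                f"unknown OAR name {name!r} (canonical {canon!r}); near matches: {near}"
            )
        return self._by_name[canon]

    def stratum_of(self, name: str) -> str:
        return self.entry(name).stratum

    def class_indices(self, stratum: str) -> Dict[str, int]:
        """name -> class index (1-based; 0 is background) for one stratum."""
        return {n: i + 1 for i, n in enumerate(self.names(stratum))}

    def n_classes(self, stratum: str) -> int:
        """Foreground class count C for one branch (background excluded)."""
        return len(self.names(stratum))

    def with_extent(self, name: str, extent_mm: Sequence[float]) -> "OARRegistry":
        canon = canonicalize_name(name)
        new = [
            replace(e, max_extent_mm=tuple(float(v) for v in extent_mm))
            if e.name == canon
            else e
            for e in self.entries
        ]
        return OARRegistry(new)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": e.name,
                    "stratum": e.stratum,
                    "laterality": e.laterality,
                    "max_extent_mm": list(e.max_extent_mm) if e.max_extent_mm else None,
                }
                for e in self.entries
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OARRegistry":
        items = json.loads(text)
        return cls(
            [
                OAREntry(
                    name=d["name"],
                    stratum=d["stratum"],
                    laterality=d.get("laterality", "none"),
                    max_extent_mm=tuple(d["max_extent_mm"]) if d.get("max_extent_mm") else None,
                )
                for d in items
            ]
        )


def _lat_pair(base: str) -> List[Tuple[str, str]]:
    return [(f"{base}_left", "left"), (f"{base}_right", "right")]


def build_registry() -> OARRegistry:
    """The canonical 42-OAR head-and-neck registry, stratified by difficulty.

    Nine anchor structures (high contrast, low inter-reader variability),
    nineteen mid-level soft-tissue structures, and fourteen small-or-hard
    structures; lateral organs count left and right separately.
    """
    anchor: List[Tuple[str, str]] = [
        ("brainstem", "none"),
        ("cerebellum", "none"),
        *_lat_pair("eye"),
        *_lat_pair("mandible"),
        ("spinal_cord", "none"),
        *_lat_pair("tmj"),
    ]
    mid: List[Tuple[str, str]] = [
        *_lat_pair("brachial_plexus"),
        *_lat_pair("basal_ganglia"),
        ("constrictor_inferior", "none"),
        ("constrictor_middle", "none"),
        ("constrictor_superior", "none"),
        ("esophagus", "none"),
        ("glottic_supraglottic_larynx", "none"),
        ("glottic_area", "none"),
        ("oral_cavity", "none"),
        *_lat_pair("parotid"),
        *_lat_pair("submandibular"),
        *_lat_pair("temporal_lobe"),
        *_lat_pair("thyroid"),
    ]
    small: List[Tuple[str, str]] = [
        *_lat_pair("cochlea"),
        ("hypothalamus", "none"),
        *_lat_pair("inner_ear"),
        *_lat_pair("lacrimal_gland"),
        *_lat_pair("lens"),
        *_lat_pair("optic_nerve"),
        ("optic_chiasm", "none"),
        ("pineal_gland", "none"),
        ("pituitary", "none"),
    ]
    entries = (
        [OAREntry(n, ANCHOR, lat) for n, lat in anchor]
        + [OAREntry(n, MID_LEVEL, lat) for n, lat in mid]
        + [OAREntry(n, SMALL_HARD, lat) for n, lat in small]
    )
    return OARRegistry(entries)


@dataclass
class TrainingSet:
    """Paired volumes and reference structure sets."""

    cases: List[Tuple[Volume, StructureSet]]

    def __post_init__(self) -> None:
        if len(self.cases) < 1:
            raise ValueError("a TrainingSet needs at least one case")

    @property
    def n(self) -> int:
        return len(self.cases)

    def validate_names(self, registry: OARRegistry) -> None:
        for i, (_, ss) in enumerate(self.cases):
            for name in ss.names():
                registry.entry(name)  # raises UnknownOARError


def measure_extents(train_set: TrainingSet, registry: OARRegistry) -> OARRegistry:
    """Fill ``max_extent_mm`` per class from the maximum bounding box observed
    across a training set's reference masks."""
    best: Dict[str, np.ndarray] = {}
    for _, ss in train_set.cases:
        for name, mask in ss.masks.items():
            if mask.is_empty():
                continue
            canon = registry.entry(name).name
            ext = np.asarray(mask.bbox_extent_mm())
            best[canon] = np.maximum(best.get(canon, np.zeros(3)), ext)
    reg = registry
    for name, ext in best.items():
        reg = reg.with_extent(name, ext)
    return reg
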