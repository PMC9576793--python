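"""The stratified segmentation pipeline.

Anchor organs are segmented directly from intensity; their predicted class
probabilities are concatenated onto the input for the mid-level branch and
for the small-structure detection module; detected peaks seed VOI crops that
the zoom-in branch segments from intensity alone, and the results are pasted
back into the full grid. ``run_inference`` chains the stages and returns one
mask per registry entry.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .core import Grid, Mask, OARRegistry, StructureSet, TrainingSet, Volume
from .localize import VOICrop, crop_voi, extract_peak, paste_voi
from .nas import Genotype
from .nn.layers import Adam, softmax_channels
from .nn.unet import UNet3D, build_fixed_unet
from .tasks import (
    ROLE_STRATUM,
    ROLES,
    build_detect_samples,
    build_seg_samples,
    mse_loss,
    normalize_intensity,
    pad_to_divisible,
    role_channels,
    seg_loss,
)


class PipelineStageError(RuntimeError):
    """An inference stage failed; the stage name is attached."""


@dataclass
class PredictionMaps:
    """Per-class probabilities (background first) on a grid."""

    probs: np.ndarray  # (C+1, D, H, W), per-voxel sums 1
    grid: Grid
    class_names: List[str]  # foreground names, index c corresponds to channel c+1

    def foreground(self) -> np.ndarray:
        return self.probs[1:]

    def argmax_masks(self) -> Dict[str, Mask]:
        labels = np.argmax(self.probs, axis=0)
        return {
            name: Mask(
                (labels == c + 1).astype(np.uint8), self.grid.spacing, self.grid.origin
            )
            for c, name in enumerate(self.class_names)
        }


@dataclass
class HeatmapSet:
    """One regressed localization heatmap per small-structure class."""

    maps: np.ndarray  # (S, D, H, W), values in [0, 1]
    grid: Grid
    class_names: List[str]


@dataclass(frozen=True)
class TrainConfig:
    """Branch training hyperparameters (CPU-scale defaults).

    By default branches train on whole (padded) volumes: the sample stream is
    then stationary, which is what lets instance-normalized features converge
    within a couple hundred Adam steps at desk scale. ``patch_size`` enables
    foreground-biased random patch sampling instead (two thirds of patches
    centred with jitter on a labelled structure) for volumes too large to fit
    in memory; patch statistics then vary per step and convergence needs more
    iterations. The zoom-in role always trains on its VOI crops.
    """

    iterations: int = 200
    lr: float = 5e-2
    patch_size: Optional[Tuple[int, int, int]] = None
    fg_patch_fraction: float = 2.0 / 3.0
    heatmap_sigma_mm: float = 3.0
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    require_all_classes: bool = True

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class BranchModel:
    """A trained network for one pipeline role."""

    role: str
    genotype: Genotype
    net: UNet3D
    class_names: List[str]
    in_channels: int
    out_channels: int
    seed: int
    config_digest: str
    loss_log: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "role": self.role,
            "genotype": json.loads(self.genotype.to_json()),
            "class_names": self.class_names,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "seed": self.seed,
            "config_digest": self.config_digest,
            "loss_log": self.loss_log,
        }
        arrays = {
            f"param_{i}": p.value for i, p in enumerate(self.net.params())
        }
        np.savez_compressed(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)

    @classmethod
    def load(cls, path: str) -> "BranchModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            genotype = Genotype.from_json(json.dumps(meta["genotype"]))
            net = build_fixed_unet(
                genotype.op_specs,
                meta["in_channels"],
                meta["out_channels"],
                genotype.levels,
                genotype.base_channels,
                seed=meta["seed"],
            )
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"param_{i}"]
        return cls(
            role=meta["role"],
            genotype=genotype,
            net=net,
            class_names=meta["class_names"],
            in_channels=meta["in_channels"],
            out_channels=meta["out_channels"],
            seed=meta["seed"],
            config_digest=meta["config_digest"],
            loss_log=list(meta["loss_log"]),
        )


def _require_role(model: BranchModel, role: str) -> None:
    if model.role != role:
        raise ValueError(f"expected a {role!r} model, got {model.role!r}")


def _forward_padded(net: UNet3D, x: np.ndarray) -> np.ndarray:
    """Pad input to the backbone's admissible shape, run, crop back."""
    factor = 2 ** (net.levels - 1)
    padded, sl = pad_to_divisible(x, factor)
    out = net.forward(padded)
    return out[(slice(None),) + sl[1:]]


def predict_anchor(x: Volume, model: BranchModel) -> PredictionMaps:
    """Anchor class probabilities at every voxel (background included)."""
    _require_role(model, "anchor_seg")
    inp = normalize_intensity(x.data)[None]
    logits = _forward_padded(model.net, inp)
    return PredictionMaps(
        softmax_channels(logits).astype(np.float32), x.grid, list(model.class_names)
    )


def reference_anchor_predictions(
    structures: StructureSet, registry: OARRegistry
) -> PredictionMaps:
    """One-hot anchor 'predictions' built from reference masks — the
    teacher-forcing guidance used when no anchor model is supplied."""
    from .tasks import anchor_guidance_from_reference

    fg = anchor_guidance_from_reference(structures, registry)
    bg = np.clip(1.0 - fg.sum(axis=0, keepdims=True), 0.0, 1.0)
    probs = np.concatenate([bg, fg], axis=0).astype(np.float32)
    return PredictionMaps(probs, structures.grid, registry.names("anchor"))


def _check_guidance(x: Volume, anchor_pred: PredictionMaps) -> None:
    if not anchor_pred.grid.approx_equal(x.grid):
        raise ValueError("anchor prediction geometry does not match the input volume")


def predict_midlevel(
    x: Volume, anchor_pred: PredictionMaps, model: BranchModel
) -> PredictionMaps:
    """Mid-level probabilities conditioned on [intensity, anchor probabilities]."""
    _require_role(model, "mid_seg")
    _check_guidance(x, anchor_pred)
    guidance = anchor_pred.foreground()
    expected = model.in_channels - 1
    if guidance.shape[0] != expected:
        raise ValueError(
            f"mid-level model expects {model.in_channels} input channels "
            f"(1 intensity + {expected} anchor classes), got guidance with "
            f"{guidance.shape[0]} channels"
        )
    inp = np.concatenate(
        [normalize_intensity(x.data)[None], guidance.astype(np.float32)], axis=0
    )
    logits = _forward_padded(model.net, inp)
    return PredictionMaps(
        softmax_channels(logits).astype(np.float32), x.grid, list(model.class_names)
    )


def predict_heatmaps(
    x: Volume, anchor_pred: PredictionMaps, model: BranchModel
) -> HeatmapSet:
    """Regressed localization heatmaps for the small-structure classes,
    clamped to [0, 1]."""
    _require_role(model, "sh_detect")
    _check_guidance(x, anchor_pred)
    guidance = anchor_pred.foreground()
    expected = model.in_channels - 1
    if guidance.shape[0] != expected:
        raise ValueError(
            f"detection model expects {model.in_channels} input channels "
            f"(1 intensity + {expected} anchor classes), got guidance with "
            f"{guidance.shape[0]} channels"
        )
    inp = np.concatenate(
        [normalize_intensity(x.data)[None], guidance.astype(np.float32)], axis=0
    )
    maps = _forward_padded(model.net, inp)
    return HeatmapSet(
        np.clip(maps, 0.0, 1.0).astype(np.float32), x.grid, list(model.class_names)
    )


def predict_sh(v: VOICrop, model: BranchModel) -> PredictionMaps:
    """Zoom-in class probabilities on the VOI grid (intensity input only)."""
    _require_role(model, "sh_seg")
    inp = normalize_intensity(v.volume.data)[None]
    logits = _forward_padded(model.net, inp)
    return PredictionMaps(
        softmax_channels(logits).astype(np.float32),
        v.volume.grid,
        list(model.class_names),
    )


def train_branch(
    train_set: TrainingSet,
    role: str,
    genotype: Genotype,
    registry: OARRegistry,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    anchor_model: Optional[BranchModel] = None,
    callback: Optional[Callable[[int, float, "BranchModel"], bool]] = None,
) -> BranchModel:
    """Train one branch network on full volumes (or VOI crops for the zoom-in
    role), cycling through cases with Adam.

    Segmentation roles optimize cross-entropy plus soft Dice; the detection
    role regresses Gaussian heatmap targets with mean squared error. When an
    anchor model is given, its predictions provide the guidance channels for
    the mid-level and detection roles; otherwise reference anchor masks are
    used as one-hot guidance. ``callback(iteration, loss, model)`` may return
    True to stop early. Reproducible given the seed.
    """
    cin, cout = role_channels(role, registry)
    stratum = ROLE_STRATUM[role]

    anchor_probs = None
    if anchor_model is not None and role in ("mid_seg", "sh_detect"):
        anchor_probs = [
            predict_anchor(vol, anchor_model).foreground()
            for vol, _ in train_set.cases
        ]

    if role == "sh_detect":
        raw = build_detect_samples(
            train_set, registry, config.heatmap_sigma_mm, anchor_probs
        )
        if not any(t.any() for _, t in raw):
            raise ValueError("no small-structure instances found for detection training")
    else:
        raw = build_seg_samples(train_set, role, registry, anchor_probs)
        if config.require_all_classes:
            covered = set()
            for _, _, present in raw:
                covered.update(present)
            indices = registry.class_indices(stratum)
            missing = [n for n, c in indices.items() if c not in covered]
            if missing:
                raise ValueError(
                    f"classes absent from every training case for role {role!r}: "
                    f"{missing}"
                )

    net = build_fixed_unet(
        genotype.op_specs, cin, cout, genotype.levels, genotype.base_channels, seed=seed
    )
    factor = 2 ** (genotype.levels - 1)
    use_patches = config.patch_size is not None and role != "sh_seg"
    if not use_patches:
        padded = []
        for sample in raw:
            xpad, _ = pad_to_divisible(sample[0], factor)
            tpad, _ = pad_to_divisible(sample[1], factor)
            padded.append((xpad, tpad) + tuple(sample[2:]))
    else:
        # per-case foreground voxel lists for foreground-biased sampling
        fg_voxels = []
        for sample in raw:
            fg = sample[1] > (0.5 if role == "sh_detect" else 0)
            if fg.ndim == 4:
                fg = fg.any(axis=0)
            fg_voxels.append(np.argwhere(fg))

    sampler = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    def sample_patch(i: int):
        x, t = raw[i][0], raw[i][1]
        shape = x.shape[1:]
        psize = [min(p, s) for p, s in zip(config.patch_size, shape)]
        if len(fg_voxels[i]) and sampler.random() < config.fg_patch_fraction:
            center = fg_voxels[i][sampler.integers(len(fg_voxels[i]))]
            jitter = sampler.integers(-4, 5, size=3)
            start = [int(c) + int(j) - p // 2 for c, j, p in zip(center, jitter, psize)]
        else:
            start = [int(sampler.integers(0, s - p + 1)) for s, p in zip(shape, psize)]
        start = [min(max(s, 0), dim - p) for s, dim, p in zip(start, shape, psize)]
        sl = tuple(slice(s, s + p) for s, p in zip(start, psize))
        xp = x[(slice(None),) + sl]
        tp = t[(slice(None),) + sl] if t.ndim == 4 else t[sl]
        xp, _ = pad_to_divisible(xp, factor)
        tp, _ = pad_to_divisible(tp, factor)
        return xp, tp

    model = BranchModel(
        role=role,
        genotype=genotype,
        net=net,
        class_names=registry.names(stratum),
        in_channels=cin,
        out_channels=cout,
        seed=seed,
        config_digest=config.digest(),
    )
    opt = Adam(net.params(), lr=config.lr)
    for it in range(config.iterations):
        i = it % len(raw)
        if use_patches:
            x, target = sample_patch(i)
            present = None
        else:
            sample = padded[i]
            x, target = sample[0], sample[1]
            present = sample[2] if len(sample) > 2 else None
        if role == "sh_detect":
            out = net.forward(x)
            loss, g = mse_loss(out, target)
        else:
            logits = net.forward(x)
            loss, g = seg_loss(
                logits,
                target,
                present,
                dice_weight=config.dice_weight,
                ce_weight=config.ce_weight,
            )
        opt.zero_grad()
        net.backward(g)
        opt.step()
        model.loss_log.append(loss)
        if callback is not None and callback(it, loss, model):
            break
    return model


def run_inference(
    x: Volume, models: Dict[str, BranchModel], registry: OARRegistry
) -> StructureSet:
    """Full-case inference: anchor, then anchor-guided mid-level and
    detection, then per-structure VOI zoom-in segmentation.

    Returns one mask per registry entry (empty where nothing was predicted);
    small-structure masks are confined to their VOI windows by construction.
    """
    for role in ("anchor_seg", "mid_seg", "sh_detect", "sh_seg"):
        if role not in models:
            raise ValueError(f"missing model for role {role!r}")
        _require_role(models[role], role)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # re-raise with the stage attached
            raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc

    anchor_pred = stage("anchor_seg", lambda: predict_anchor(x, models["anchor_seg"]))
    mid_pred = stage(
        "mid_seg", lambda: predict_midlevel(x, anchor_pred, models["mid_seg"])
    )
    heat = stage(
        "sh_detect", lambda: predict_heatmaps(x, anchor_pred, models["sh_detect"])
    )

    masks: Dict[str, Mask] = {}
    masks.update(stage("anchor_seg", anchor_pred.argmax_masks))
    masks.update(stage("mid_seg", mid_pred.argmax_masks))

    sh_indices = registry.class_indices("small_hard")
    for k, name in enumerate(heat.class_names):
        entry = registry.entry(name)
        if entry.max_extent_mm is None:
            # without a learned extent there is no VOI to zoom into
            warnings.warn(
                f"no max_extent_mm for {name!r}: emitting an empty mask",
                stacklevel=2,
            )
            masks[name] = Mask(
                np.zeros(x.grid.shape, dtype=np.uint8), x.spacing, x.origin
            )
            continue

        def sh_stage(k=k, name=name, entry=entry):
            peak = extract_peak(heat.maps[k])
            crop = crop_voi(x, peak, entry)
            pred = predict_sh(crop, models["sh_seg"])
            return paste_voi(x.grid, pred.probs, crop, sh_indices[name])

        masks[name] = stage(f"sh_seg[{name}]", sh_stage)

    return StructureSet(masks, x.grid)
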