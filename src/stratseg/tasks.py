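"""Branch task assembly: network inputs, label maps, and loss functions.

Each branch is one multi-class problem over its stratum's classes plus
background (index 0). The mid-level and detection branches receive the
anchor class probabilities as extra input channels next to the intensity
channel; the small-structure zoom-in branch sees only the cropped intensity.

Losses are the community-standard pairing: cross-entropy plus soft Dice for
segmentation, mean squared error for heatmap regression. Both return the
loss value and its gradient with respect to the network output.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Mask, OARRegistry, StructureSet, TrainingSet, Volume
from .nn.layers import softmax_channels

ROLES = ("anchor_seg", "mid_seg", "sh_detect", "sh_seg")

ROLE_STRATUM = {
    "anchor_seg": "anchor",
    "mid_seg": "mid-level",
    "sh_detect": "small_hard",
    "sh_seg": "small_hard",
}


def role_channels(role: str, registry: OARRegistry) -> Tuple[int, int]:
    """(input channels, output channels) contract for a branch role."""
    c_anchor = registry.n_classes("anchor")
    if role == "anchor_seg":
        return 1, registry.n_classes("anchor") + 1
    if role == "mid_seg":
        return 1 + c_anchor, registry.n_classes("mid-level") + 1
    if role == "sh_detect":
        return 1 + c_anchor, registry.n_classes("small_hard")
    if role == "sh_seg":
        return 1, registry.n_classes("small_hard") + 1
    raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")


def normalize_intensity(data: np.ndarray) -> np.ndarray:
    """Per-volume z-scoring of the intensity channel."""
    x = np.asarray(data, dtype=np.float32)
    std = float(x.std())
    return (x - float(x.mean())) / (std if std > 0 else 1.0)


def label_map(
    structures: StructureSet,
    registry: OARRegistry,
    stratum: str,
    shape: Tuple[int, int, int],
) -> Tuple[np.ndarray, List[int]]:
    """Integer class map for one stratum plus the class indices present.

    Later registry entries overwrite earlier ones at (unexpected) voxel
    conflicts; generation forbids overlap so this is a formality.
    """
    indices = registry.class_indices(stratum)
    labels = np.zeros(shape, dtype=np.int64)
    present: List[int] = []
    for name in structures.names():
        entry = registry.entry(name)
        if entry.stratum != stratum:
            continue
        cls = indices[entry.name]
        mask = structures[name]
        if mask.data.any():
            labels[mask.data > 0] = cls
            present.append(cls)
    return labels, sorted(present)


def anchor_guidance_from_reference(
    structures: StructureSet, registry: OARRegistry
) -> np.ndarray:
    """One-hot anchor class channels from reference masks (training-time
    surrogate for the anchor branch's predicted probabilities)."""
    names = registry.names("anchor")
    shape = structures.grid.shape
    out = np.zeros((len(names),) + tuple(shape), dtype=np.float32)
    for i, name in enumerate(names):
        if name in structures:
            out[i] = structures[name].data
    return out


def assemble_input(
    volume: Volume,
    role: str,
    registry: OARRegistry,
    anchor_probs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stack the network input channels for a role.

    ``anchor_probs`` are the anchor foreground class probability channels
    (background excluded), required for the mid-level and detection roles.
    """
    x = normalize_intensity(volume.data)[None]
    cin, _ = role_channels(role, registry)
    if role in ("anchor_seg", "sh_seg"):
        return x
    if anchor_probs is None:
        raise ValueError(f"role {role!r} requires anchor guidance channels")
    want = cin - 1
    if anchor_probs.shape[0] != want or anchor_probs.shape[1:] != x.shape[1:]:
        raise ValueError(
            f"anchor guidance must have shape ({want},) + {x.shape[1:]}, "
            f"got {anchor_probs.shape}"
        )
    return np.concatenate([x, anchor_probs.astype(np.float32)], axis=0)


# ---------------------------------------------------------------------------
# losses


def seg_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    present_classes: Optional[Sequence[int]] = None,
    dice_weight: float = 1.0,
    ce_weight: float = 1.0,
    class_balance: bool = True,
    max_class_weight: float = 200.0,
    eps: float = 1e-6,
) -> Tuple[float, np.ndarray]:
    """Cross-entropy + soft-Dice loss and its gradient w.r.t. the logits.

    With ``class_balance`` the cross-entropy is voxel-weighted so every label
    value present contributes equally regardless of its volume (weights capped
    at ``max_class_weight``); organs occupy well under 1% of a head-and-neck
    field of view, and unweighted voxel losses stall on the background class
    at desk-scale iteration counts. The Dice term averages over foreground
    classes with reference voxels (``present_classes`` when given), so cases
    annotated with a subset of the stratum's organs still produce a
    well-defined objective.
    """
    C = logits.shape[0]
    n = int(np.prod(labels.shape))
    p = softmax_channels(logits.astype(np.float64))
    pf = p.reshape(C, n)
    lab = labels.reshape(n)

    if class_balance:
        counts = np.bincount(lab, minlength=C).astype(np.float64)
        present = counts > 0
        k = int(present.sum())
        class_w = np.zeros(C)
        class_w[present] = np.minimum(n / (k * counts[present]), max_class_weight)
        w = class_w[lab]
    else:
        w = np.ones(n)
    wsum = float(w.sum())

    logp = np.log(pf[lab, np.arange(n)] + 1e-12)
    ce = -float((w * logp).sum() / wsum)
    onehot_grad = np.zeros_like(pf)
    onehot_grad[lab, np.arange(n)] = 1.0
    g_logits = ce_weight * (w[None, :] * (pf - onehot_grad)) / wsum

    fg = [c for c in range(1, C) if (lab == c).any()]
    if present_classes is not None:
        fg = [c for c in fg if c in set(present_classes)]
    dice_val = 0.0
    if fg and dice_weight > 0:
        gp = np.zeros_like(pf)
        dices = []
        for c in fg:
            y = (lab == c).astype(np.float64)
            pc = pf[c]
            inter = float((pc * y).sum())
            s, t = float(pc.sum()), float(y.sum())
            d = (2 * inter + eps) / (s + t + eps)
            dices.append(d)
            gp[c] = -(2 * y * (s + t + eps) - (2 * inter + eps)) / (s + t + eps) ** 2
        dice_val = 1.0 - float(np.mean(dices))
        gp /= len(fg)
        # chain rule through the softmax
        dot = (gp * pf).sum(axis=0, keepdims=True)
        g_logits = g_logits + dice_weight * pf * (gp - dot)

    loss = ce_weight * ce + dice_weight * dice_val
    return float(loss), g_logits.reshape(logits.shape).astype(np.float32)


def mse_loss(
    pred: np.ndarray,
    target: np.ndarray,
    balance: bool = True,
    fg_threshold: float = 0.05,
    max_fg_weight: float = 500.0,
) -> Tuple[float, np.ndarray]:
    """(Weighted) mean squared error and its gradient w.r.t. the prediction.

    With ``balance`` voxels under a Gaussian bump (target above
    ``fg_threshold``) are up-weighted so foreground and background contribute
    equally; a bump covers a vanishing fraction of the volume and an
    unweighted regression collapses to the all-zero map.
    """
    diff = pred.astype(np.float64) - target.astype(np.float64)
    if balance:
        fg = np.asarray(target) > fg_threshold
        n_fg, n_bg = int(fg.sum()), int((~fg).sum())
        w = np.ones(diff.shape)
        if 0 < n_fg < diff.size:
            w[fg] = min(n_bg / n_fg, max_fg_weight)
        wsum = float(w.sum())
        loss = float((w * diff**2).sum() / wsum)
        return loss, (2.0 * w * diff / wsum).astype(np.float32)
    n = diff.size
    loss = float((diff**2).mean())
    return loss, (2.0 * diff / n).astype(np.float32)


# ---------------------------------------------------------------------------
# sample assembly


def pad_to_divisible(
    arr: np.ndarray, factor: int, min_size: Optional[int] = None
) -> Tuple[np.ndarray, Tuple[slice, ...]]:
    """Zero-pad the trailing three axes so each is a multiple of ``factor``
    (and at least ``min_size``); returns the padded array and the slices that
    recover the original region."""
    min_size = min_size or 2 * factor
    spatial = arr.shape[-3:]
    target = [max(min_size, -(-s // factor) * factor) for s in spatial]
    pads = [(0, t - s) for s, t in zip(spatial, target)]
    lead = [(0, 0)] * (arr.ndim - 3)
    padded = np.pad(arr, lead + pads)
    sl = tuple([slice(None)] * (arr.ndim - 3) + [slice(0, s) for s in spatial])
    return padded, sl


def build_seg_samples(
    train_set: TrainingSet,
    role: str,
    registry: OARRegistry,
    anchor_probs: Optional[List[np.ndarray]] = None,
) -> List[Tuple[np.ndarray, np.ndarray, List[int]]]:
    """Per-case (input, label map, present classes) for a segmentation role.

    For the zoom-in role each small-structure instance becomes its own
    VOI-cropped sample (intensity channel only); the other roles train on
    whole volumes. The zoom-in crops require per-class extents, which are
    measured from the training labels when the registry lacks them.
    """
    stratum = ROLE_STRATUM[role]
    samples: List[Tuple[np.ndarray, np.ndarray, List[int]]] = []
    if role == "sh_seg":
        from .core import measure_extents
        from .localize import crop_voi

        needs_extents = any(
            registry.entry(n).stratum == stratum
            and registry.entry(n).max_extent_mm is None
            for _, ss in train_set.cases
            for n in ss.names()
        )
        if needs_extents:
            registry = measure_extents(train_set, registry)
        for vol, ss in train_set.cases:
            for name in ss.names():
                entry = registry.entry(name)
                if entry.stratum != stratum or ss[name].is_empty():
                    continue
                crop = crop_voi(vol, ss[name].centroid_voxel(), entry)
                sub_ss = StructureSet(
                    {
                        n: Mask(
                            ss[n].data[crop.slices()],
                            vol.spacing,
                            crop.volume.origin,
                        )
                        for n in ss.names()
                        if registry.entry(n).stratum == stratum
                    },
                    crop.volume.grid,
                )
                labels, present = label_map(sub_ss, registry, stratum, crop.size)
                x = assemble_input(crop.volume, role, registry)
                samples.append((x, labels, present))
        if not samples:
            raise ValueError("no small-structure instances found in the training set")
        return samples

    for i, (vol, ss) in enumerate(train_set.cases):
        guidance = anchor_probs[i] if anchor_probs is not None else None
        if role in ("mid_seg", "sh_detect") and guidance is None:
            guidance = anchor_guidance_from_reference(ss, registry)
        x = assemble_input(vol, role, registry, anchor_probs=guidance)
        labels, present = label_map(ss, registry, stratum, vol.data.shape)
        samples.append((x, labels, present))
    return samples


def build_detect_samples(
    train_set: TrainingSet,
    registry: OARRegistry,
    sigma_mm: float = 3.0,
    anchor_probs: Optional[List[np.ndarray]] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Per-case (input, heatmap target stack) for the detection module.

    One Gaussian bump per small-structure class at the mask centroid; classes
    absent from a case get an all-zero target channel.
    """
    from .localize import gaussian_target

    names = registry.names("small_hard")
    samples = []
    for i, (vol, ss) in enumerate(train_set.cases):
        guidance = anchor_probs[i] if anchor_probs is not None else None
        if guidance is None:
            guidance = anchor_guidance_from_reference(ss, registry)
        x = assemble_input(vol, "sh_detect", registry, anchor_probs=guidance)
        target = np.zeros((len(names),) + vol.data.shape, dtype=np.float32)
        for k, name in enumerate(names):
            if name in ss and not ss[name].is_empty():
                target[k] = gaussian_target(
                    ss[name].centroid_voxel(), sigma_mm, vol.grid
                )
        samples.append((x, target))
    return samples
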