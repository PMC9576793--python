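"""Differentiable search over the six convolution operators per block.

Each searchable block owns a vector of six learnable logits alpha; the
softmax weights gamma_k = exp(alpha_k) / sum_m exp(alpha_m) mix the
candidate operator outputs, phi' = sum_k gamma_k phi_k. Search alternates
first-order gradient steps on the network weights (on one data partition)
and on the logits (on a disjoint partition); the discrete genotype keeps,
per block, the operator with the top weight, ties broken toward the lowest
index in the fixed ordering (2D3, 2D5, 3D3, 3D5, P3D3, P3D5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import OARRegistry, TrainingSet
from .nn.layers import Adam, Param
from .nn.ops import N_OPS, OP_ORDER, OpSpec
from .nn.unet import block_ids, build_search_unet
from .tasks import role_channels, seg_loss


def gamma_weights(alphas: np.ndarray) -> np.ndarray:
    """Softmax operator weights for one block's logits (max-subtracted)."""
    a = np.asarray(alphas, dtype=np.float64)
    if a.shape != (N_OPS,):
        raise ValueError(f"expected {N_OPS} logits, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("architecture logits must be finite")
    e = np.exp(a - a.max())
    return e / e.sum()


def mixed_block_forward(x: np.ndarray, ops, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of candidate operator outputs (the continuous relaxation)."""
    weights = np.asarray(weights, dtype=np.float64)
    outs = [op.forward(x) for op in ops]
    shapes = {o.shape for o in outs}
    if len(shapes) != 1:
        raise ValueError(f"candidate outputs disagree in shape: {sorted(shapes)}")
    mixed = np.zeros(outs[0].shape, dtype=outs[0].dtype)
    for w, o in zip(weights, outs):
        mixed += w * o
    return mixed


@dataclass
class SearchState:
    """Per-block architecture logits."""

    alphas: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for bid, a in self.alphas.items():
            arr = np.asarray(a, dtype=np.float64)
            if arr.shape != (N_OPS,):
                raise ValueError(f"block {bid!r}: expected {N_OPS} logits")
            if not np.isfinite(arr).all():
                raise ValueError(f"block {bid!r}: logits must be finite")
            self.alphas[bid] = arr

    @classmethod
    def uniform(cls, ids: List[str]) -> "SearchState":
        return cls({bid: np.zeros(N_OPS) for bid in ids})

    def gammas(self) -> Dict[str, np.ndarray]:
        return {bid: gamma_weights(a) for bid, a in self.alphas.items()}


@dataclass
class Genotype:
    """Discrete architecture: one operator choice per block plus backbone size."""

    op_specs: Dict[str, OpSpec]
    levels: int = 2
    base_channels: int = 8

    def to_json(self) -> str:
        return json.dumps(
            {
                "levels": self.levels,
                "base_channels": self.base_channels,
                "blocks": {
                    bid: {"kind": s.kind, "kernel": s.kernel}
                    for bid, s in self.op_specs.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Genotype":
        d = json.loads(text)
        return cls(
            op_specs={
                bid: OpSpec(v["kind"], v["kernel"]) for bid, v in d["blocks"].items()
            },
            levels=d["levels"],
            base_channels=d["base_channels"],
        )

    @classmethod
    def uniform(cls, kind: str, kernel: int, levels: int, base_channels: int) -> "Genotype":
        spec = OpSpec(kind, kernel)
        return cls(
            {bid: spec for bid in block_ids(levels)},
            levels=levels,
            base_channels=base_channels,
        )


def derive_genotype(
    state: SearchState, levels: int = 2, base_channels: int = 8
) -> Genotype:
    """Per block, keep the operator with maximal weight (equivalently maximal
    logit, softmax being order-preserving); np.argmax's first-maximum rule
    implements the lowest-index tie-break."""
    specs = {}
    for bid, a in state.alphas.items():
        k = int(np.argmax(a))
        specs[bid] = OpSpec(*OP_ORDER[k])
    return Genotype(specs, levels=levels, base_channels=base_channels)


@dataclass(frozen=True)
class SearchConfig:
    """Search hyperparameters (small CPU-friendly defaults)."""

    levels: int = 2
    base_channels: int = 8
    epochs: int = 5
    lr_weights: float = 1e-2
    lr_alphas: float = 3e-2
    weight_fraction: float = 2.0 / 3.0  # case-level weight/architecture split


@dataclass
class SearchLog:
    epochs: List[int] = field(default_factory=list)
    weight_losses: List[float] = field(default_factory=list)
    arch_losses: List[float] = field(default_factory=list)
    gamma_history: List[Dict[str, np.ndarray]] = field(default_factory=list)

    def to_table(self):
        import pandas as pd

        rows = []
        for i, ep in enumerate(self.epochs):
            row = {
                "epoch": ep,
                "weight_loss": self.weight_losses[i],
                "arch_loss": self.arch_losses[i],
            }
            for bid, g in self.gamma_history[i].items():
                for k, (kind, kern) in enumerate(OP_ORDER):
                    row[f"gamma.{bid}.{kind}{kern}"] = g[k]
            rows.append(row)
        return pd.DataFrame(rows)


def split_cases(n: int, weight_fraction: float) -> Tuple[List[int], List[int]]:
    """Disjoint case-level partition: leading cases update weights, trailing
    cases update the architecture logits."""
    n_w = int(round(n * weight_fraction))
    n_w = min(max(n_w, 1), n - 1) if n >= 2 else 0
    weight_idx = list(range(n_w))
    arch_idx = list(range(n_w, n))
    if not weight_idx or not arch_idx:
        raise ValueError(
            f"cannot split {n} cases into nonempty weight/architecture partitions"
        )
    return weight_idx, arch_idx


def search_architecture(
    train_set: TrainingSet,
    role: str,
    registry: OARRegistry,
    config: SearchConfig = SearchConfig(),
    seed: int = 0,
    log: Optional[SearchLog] = None,
) -> Genotype:
    """Alternating first-order search; returns the derived discrete genotype.

    With zero epochs nothing is learned and the uniform logits fall back to
    the first operator everywhere. Fully reproducible given the seed.
    """
    from .tasks import build_seg_samples  # local import avoids a cycle

    cin, cout = role_channels(role, registry)
    if role == "sh_detect":
        raise ValueError("the detection module is not architecture-searched")
    samples = build_seg_samples(train_set, role, registry)

    net = build_search_unet(
        cin, cout, config.levels, config.base_channels, seed=seed
    )
    ids = net.mixed_block_ids()
    state = SearchState.uniform(ids)
    if config.epochs <= 0:
        return derive_genotype(state, config.levels, config.base_channels)

    weight_idx, arch_idx = split_cases(len(samples), config.weight_fraction)
    opt_w = Adam(net.params(), lr=config.lr_weights)
    alpha_params = {bid: Param(state.alphas[bid]) for bid in ids}
    opt_a = Adam(list(alpha_params.values()), lr=config.lr_alphas)

    for epoch in range(config.epochs):
        gammas = state.gammas()
        w_losses = []
        for i in weight_idx:
            x, labels, present = samples[i]
            logits = net.forward(x, gammas=gammas)
            loss, g = seg_loss(logits, labels, present)
            w_losses.append(loss)
            opt_w.zero_grad()
            net.backward(g)
            opt_w.step()
        a_losses = []
        for i in arch_idx:
            x, labels, present = samples[i]
            gammas = state.gammas()
            logits = net.forward(x, gammas=gammas)
            loss, g = seg_loss(logits, labels, present)
            a_losses.append(loss)
            opt_a.zero_grad()
            net.backward(g)
            ggam = net.gamma_grads()
            for bid in ids:
                gam = gammas[bid]
                gg = ggam[bid]
                alpha_params[bid].grad += gam * (gg - float((gam * gg).sum()))
            opt_a.step()
        for bid in ids:
            state.alphas[bid] = alpha_params[bid].value
        if log is not None:
            log.epochs.append(epoch)
            log.weight_losses.append(float(np.mean(w_losses)))
            log.arch_losses.append(float(np.mean(a_losses)))
            log.gamma_history.append(state.gammas())

    return derive_genotype(state, config.levels, config.base_channels)
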