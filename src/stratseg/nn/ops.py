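"""Candidate convolution operators and the softmax-weighted mixed block.

The search space holds six composite operators, each "convolution ->
instance normalization -> leaky rectifier":

* 2D, kernel 3 or 5 — in-plane kernel (1, k, k); the through-plane extent is 1
* 3D, kernel 3 or 5 — isotropic kernel (k, k, k)
* pseudo-3D (P3D), kernel 3 or 5 — an in-plane composite (1, k, k) chained
  with a through-plane composite (k, 1, 1)

The fixed ordering (2D3, 2D5, 3D3, 3D5, P3D3, P3D5) defines tie-breaking and
serialization everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .layers import Conv3d, InstanceNorm, Layer, LeakyReLU, Param

OP_ORDER: Tuple[Tuple[str, int], ...] = (
    ("2D", 3),
    ("2D", 5),
    ("3D", 3),
    ("3D", 5),
    ("P3D", 3),
    ("P3D", 5),
)
N_OPS = len(OP_ORDER)


@dataclass(frozen=True)
class OpSpec:
    kind: str  # "2D" | "3D" | "P3D"
    kernel: int  # 3 | 5

    def __post_init__(self) -> None:
        if self.kind not in ("2D", "3D", "P3D"):
            raise ValueError(f"unknown op kind {self.kind!r}")
        if self.kernel not in (3, 5):
            raise ValueError(f"kernel must be 3 or 5, got {self.kernel}")

    @property
    def index(self) -> int:
        return OP_ORDER.index((self.kind, self.kernel))

    def kernels(self) -> List[Tuple[int, int, int]]:
        k = self.kernel
        if self.kind == "2D":
            return [(1, k, k)]
        if self.kind == "3D":
            return [(k, k, k)]
        return [(1, k, k), (k, 1, 1)]  # P3D: in-plane then through-plane


class CompositeOp(Layer):
    """conv -> instance norm -> leaky ReLU, possibly chained twice (P3D)."""

    def __init__(
        self,
        spec: OpSpec,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.spec = spec
        self.stages: List[List[Layer]] = []
        cin = in_channels
        for kernel in spec.kernels():
            self.stages.append(
                [
                    Conv3d(cin, out_channels, kernel, rng, dtype=dtype),
                    InstanceNorm(out_channels, dtype=dtype),
                    LeakyReLU(),
                ]
            )
            cin = out_channels

    def params(self) -> List[Param]:
        return [p for stage in self.stages for layer in stage for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for stage in self.stages:
            for layer in stage:
                x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for stage in reversed(self.stages):
            for layer in reversed(stage):
                gout = layer.backward(gout)
        return gout


def make_candidates(
    in_channels: int, out_channels: int, rng: np.random.Generator, dtype=np.float32
) -> List[CompositeOp]:
    """All six search-space operators with independent parameters."""
    return [
        CompositeOp(OpSpec(kind, k), in_channels, out_channels, rng, dtype=dtype)
        for kind, k in OP_ORDER
    ]


class MixedBlock(Layer):
    """Convex combination of the six candidate operators.

    ``forward`` takes the operator weights (a probability vector from the
    softmax over the block's architecture logits); ``backward`` returns the
    input gradient and stores the gradient with respect to the weights in
    ``gamma_grad``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.ops = make_candidates(in_channels, out_channels, rng, dtype=dtype)
        self.gamma_grad: Optional[np.ndarray] = None
        self._cache: Optional[Tuple] = None

    def params(self) -> List[Param]:
        return [p for op in self.ops for p in op.params()]

    def forward(self, x: np.ndarray, gammas: np.ndarray) -> np.ndarray:
        gammas = np.asarray(gammas, dtype=np.float64)
        if gammas.shape != (N_OPS,):
            raise ValueError(f"expected {N_OPS} weights, got shape {gammas.shape}")
        outs = [op.forward(x) for op in self.ops]
        ref_shape = outs[0].shape
        for o, op in zip(outs, self.ops):
            if o.shape != ref_shape:
                raise ValueError(
                    f"candidate {op.spec} output shape {o.shape} != {ref_shape}"
                )
        mixed = np.zeros(ref_shape, dtype=outs[0].dtype)
        for g, o in zip(gammas, outs):
            mixed += g * o
        self._cache = (outs, gammas)
        return mixed

    def backward(self, gout: np.ndarray) -> np.ndarray:
        outs, gammas = self._cache
        self.gamma_grad = np.array(
            [float((gout * o).sum()) for o in outs], dtype=np.float64
        )
        gx = None
        for g, op in zip(gammas, self.ops):
            gi = op.backward((g * gout).astype(gout.dtype, copy=False))
            gx = gi if gx is None else gx + gi
        return gx
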