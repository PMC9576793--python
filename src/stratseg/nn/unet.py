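"""Encoder-decoder segmentation backbone with searchable convolution blocks.

A U-Net-style network: ``levels`` resolution stages connected by 2x average
pooling and nearest-neighbour upsampling, skip connections concatenated and
compressed by a 1x1x1 convolution, and one convolution block per stage. The
per-stage blocks are either fixed composite operators (from a genotype) or
mixed blocks holding all six candidates (during architecture search). The
1x1x1 compression keeps decoder widths small, which keeps CPU training of
desk-scale volumes inside minutes.

Block identifiers are ``enc0..enc{L-1}`` then ``dec{L-2}..dec0``.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .layers import AvgPool2, Conv3d, Layer, Param, Upsample2
from .ops import CompositeOp, MixedBlock, OpSpec


def block_ids(levels: int) -> List[str]:
    return [f"enc{l}" for l in range(levels)] + [
        f"dec{l}" for l in range(levels - 2, -1, -1)
    ]


def min_admissible_shape(levels: int) -> Tuple[int, int, int]:
    m = 2**levels
    return (m, m, m)


def check_shape(shape: Tuple[int, int, int], levels: int) -> None:
    factor = 2 ** (levels - 1)
    ok = all(s % factor == 0 and s // factor >= 2 for s in shape)
    if not ok:
        raise ValueError(
            f"spatial shape {tuple(shape)} too small or not divisible by "
            f"{factor} for a {levels}-level backbone; minimum admissible shape "
            f"is {min_admissible_shape(levels)} with all extents multiples of {factor}"
        )


class UNet3D:
    """Backbone over (C, D, H, W) grids; output preserves the spatial shape."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        levels: int,
        base_channels: int,
        make_block: Callable[[str, int, int, np.random.Generator], Layer],
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        if levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if in_channels < 1 or out_channels < 1 or base_channels < 1:
            raise ValueError("channel counts must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.levels = levels
        self.base_channels = base_channels

        width = [base_channels * 2**l for l in range(levels)]
        self.blocks: Dict[str, Layer] = {}
        for l in range(levels):
            cin = in_channels if l == 0 else width[l - 1]
            self.blocks[f"enc{l}"] = make_block(f"enc{l}", cin, width[l], rng)
        self.pool = AvgPool2()
        self.up = Upsample2()
        self.compress: Dict[str, Conv3d] = {}
        for l in range(levels - 2, -1, -1):
            cat_ch = width[l] + width[l + 1]
            self.compress[f"dec{l}"] = Conv3d(cat_ch, width[l], (1, 1, 1), rng, dtype=dtype)
            self.blocks[f"dec{l}"] = make_block(f"dec{l}", width[l], width[l], rng)
        self.head = Conv3d(width[0], out_channels, (1, 1, 1), rng, dtype=dtype)
        self._cache: Optional[Dict] = None

    def params(self) -> List[Param]:
        out: List[Param] = []
        for bid in block_ids(self.levels):
            out.extend(self.blocks[bid].params())
            if bid in self.compress:
                out.extend(self.compress[bid].params())
        out.extend(self.head.params())
        return out

    def n_params(self) -> int:
        return sum(int(np.prod(p.value.shape)) for p in self.params())

    def _block_forward(self, bid: str, x, gammas):
        block = self.blocks[bid]
        if isinstance(block, MixedBlock):
            if gammas is None or bid not in gammas:
                raise ValueError(f"mixed block {bid!r} needs operator weights")
            return block.forward(x, gammas[bid])
        return block.forward(x)

    def forward(
        self, x: np.ndarray, gammas: Optional[Dict[str, np.ndarray]] = None
    ) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected input of shape ({self.in_channels}, D, H, W), got {x.shape}"
            )
        check_shape(x.shape[1:], self.levels)
        L = self.levels
        skips: List[np.ndarray] = []
        h = x
        for l in range(L):
            h = self._block_forward(f"enc{l}", h, gammas)
            skips.append(h)
            if l < L - 1:
                h = self.pool.forward(h)
        cat_channels: Dict[str, Tuple[int, int]] = {}
        for l in range(L - 2, -1, -1):
            bid = f"dec{l}"
            h = self.up.forward(h)
            skip = skips[l]
            cat = np.concatenate([skip, h], axis=0)
            cat_channels[bid] = (skip.shape[0], h.shape[0])
            h = self.compress[bid].forward(cat)
            h = self._block_forward(bid, h, gammas)
        out = self.head.forward(h)
        self._cache = {"cat_channels": cat_channels}
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        L = self.levels
        cat_channels = self._cache["cat_channels"]
        g = self.head.backward(gout)
        gskips: Dict[int, np.ndarray] = {}
        for l in range(0, L - 1):
            bid = f"dec{l}"
            g = self.blocks[bid].backward(g)
            gcat = self.compress[bid].backward(g)
            n_skip, _ = cat_channels[bid]
            gskips[l] = gcat[:n_skip]
            g = self.up.backward(gcat[n_skip:])
        for l in range(L - 1, -1, -1):
            if l < L - 1:
                g = self.pool.backward(g)
                g = g + gskips[l]
            g = self.blocks[f"enc{l}"].backward(g)
        return g

    # architecture-search helpers ------------------------------------------

    def mixed_block_ids(self) -> List[str]:
        return [
            bid
            for bid in block_ids(self.levels)
            if isinstance(self.blocks[bid], MixedBlock)
        ]

    def gamma_grads(self) -> Dict[str, np.ndarray]:
        return {
            bid: self.blocks[bid].gamma_grad
            for bid in self.mixed_block_ids()
        }


def build_fixed_unet(
    op_specs: Dict[str, OpSpec],
    in_channels: int,
    out_channels: int,
    levels: int,
    base_channels: int,
    seed: int,
    dtype=np.float32,
) -> UNet3D:
    """Construct a backbone whose blocks are the given fixed operators."""
    rng = np.random.default_rng(seed)
    missing = [bid for bid in block_ids(levels) if bid not in op_specs]
    if missing:
        raise ValueError(f"genotype missing operator choices for blocks: {missing}")

    def make_block(bid: str, cin: int, cout: int, r: np.random.Generator):
        return CompositeOp(op_specs[bid], cin, cout, r, dtype=dtype)

    return UNet3D(in_channels, out_channels, levels, base_channels, make_block, rng, dtype)


def build_search_unet(
    in_channels: int,
    out_channels: int,
    levels: int,
    base_channels: int,
    seed: int,
    dtype=np.float32,
) -> UNet3D:
    """Construct a backbone with all-candidate mixed blocks for search."""
    rng = np.random.default_rng(seed)

    def make_block(bid: str, cin: int, cout: int, r: np.random.Generator):
        return MixedBlock(cin, cout, r, dtype=dtype)

    return UNet3D(in_channels, out_channels, levels, base_channels, make_block, rng, dtype)
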