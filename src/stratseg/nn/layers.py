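"""Minimal 3D neural-network layers in NumPy with explicit backward passes.

Tensors are single-sample feature grids of shape (C, D, H, W). Convolution
is same-padded cross-correlation implemented as a flat-shift im2col: shifted
windows of the zero-padded input are contiguous slices of its flattened
array, so building the column matrix is a set of memcpys followed by one
BLAS GEMM per z-chunk. Workspaces are cached in a module-level arena so the
large buffers are allocated (and page-faulted) once per shape.

Every layer implements ``forward(x)`` and ``backward(gout)``; parameter
gradients accumulate into ``Param.grad`` and are consumed by the optimizer.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

_ARENA: Dict[Tuple, np.ndarray] = {}


def _workspace(key: str, shape: Tuple[int, ...], dtype) -> np.ndarray:
    """Reusable scratch buffer; contents are undefined on entry."""
    k = (key, shape, np.dtype(dtype).str)
    buf = _ARENA.get(k)
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        _ARENA[k] = buf
    return buf


def clear_workspaces() -> None:
    _ARENA.clear()


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padded 3D cross-correlation with bias.

    ``kernel`` is (kz, ky, kx) with odd entries; entries of 1 make the
    receptive field collapse along that axis (e.g. (1, 3, 3) is an in-plane
    2D convolution).
    """

    # target size for the column-matrix chunk, in float32 elements
    _CHUNK_BUDGET = 24_000_000

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: Tuple[int, int, int],
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        if any(k < 1 or k % 2 == 0 for k in kernel):
            raise ValueError(f"kernel entries must be odd and >= 1, got {kernel}")
        self.cin, self.cout, self.kernel = in_channels, out_channels, tuple(kernel)
        fan_in = in_channels * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.W = Param((rng.standard_normal((out_channels, fan_in)) * scale).astype(dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self._cache: Optional[Tuple] = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    @property
    def weight_tensor(self) -> np.ndarray:
        kz, ky, kx = self.kernel
        return self.W.value.reshape(self.cout, kz, ky, kx, self.cin).transpose(
            0, 4, 1, 2, 3
        )

    def _offsets(self, Hp: int, Wp: int) -> List[int]:
        kz, ky, kx = self.kernel
        return [
            (dz * Hp + dy) * Wp + dx
            for dz in range(kz)
            for dy in range(ky)
            for dx in range(kx)
        ]

    def _plan(self, shape: Tuple[int, int, int]):
        D, H, Wd = shape
        kz, ky, kx = self.kernel
        pz, py, px = kz // 2, ky // 2, kx // 2
        Hp, Wp = H + 2 * py, Wd + 2 * px
        K = kz * ky * kx
        rows = K * self.cin
        plane = Hp * Wp
        chunk = max(1, min(D, self._CHUNK_BUDGET // max(1, rows * plane)))
        return (pz, py, px), (Hp, Wp), K, rows, plane, chunk

    def forward(self, x: np.ndarray) -> np.ndarray:
        # Column rows are ordered offset-major, channel-minor: row k*cin + c
        # holds channel c shifted by kernel offset k; self.W stores weights
        # as (cout, K*cin) in the same order.
        if x.shape[0] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[0]}")
        D, H, Wd = x.shape[1:]
        (pz, py, px), (Hp, Wp), K, rows, plane, chunk = self._plan(x.shape[1:])
        xp = np.pad(x, ((0, 0), (pz, pz), (py, py), (px, px)))
        xpf = xp.reshape(self.cin, -1)  # contiguous per-channel flat view
        offs = self._offsets(Hp, Wp)
        Wm = self.W.value

        out_flat = _workspace(("fwd", id(self)), (self.cout, D * plane), x.dtype)
        col = _workspace(("col", id(self)), (rows, chunk * plane), x.dtype)
        for z0 in range(0, D, chunk):
            z1 = min(z0 + chunk, D)
            cz = z1 - z0
            span = (cz - 1) * plane + (H - 1) * Wp + Wd
            base = z0 * plane
            for k, off in enumerate(offs):
                col[k * self.cin : (k + 1) * self.cin, :span] = xpf[
                    :, base + off : base + off + span
                ]
            out_flat[:, base : base + span] = Wm @ col[:, :span]
        out = out_flat.reshape(self.cout, D, Hp, Wp)[:, :, :H, :Wd]
        out = out + self.b.value[:, None, None, None]
        self._cache = (xp, x.shape[1:])
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        xp, shape = self._cache
        D, H, Wd = shape
        (pz, py, px), (Hp, Wp), K, rows, plane, chunk = self._plan(shape)
        offs = self._offsets(Hp, Wp)
        Wm = self.W.value
        xpf = xp.reshape(self.cin, -1)

        self.b.grad += gout.sum(axis=(1, 2, 3))

        # zero-padded gradient on the padded-plane layout; garbage columns in
        # the y/x pad region stay zero so GEMM contributions are exact
        g_pad = _workspace(("gpad", id(self)), (self.cout, D, Hp, Wp), gout.dtype)
        g_pad[...] = 0
        g_pad[:, :, :H, :Wd] = gout
        g_flat_all = g_pad.reshape(self.cout, -1)

        gxp = np.zeros_like(xp)
        gxpf = gxp.reshape(self.cin, -1)
        col = _workspace(("col", id(self)), (rows, chunk * plane), xp.dtype)
        gW = np.zeros_like(self.W.value)
        for z0 in range(0, D, chunk):
            z1 = min(z0 + chunk, D)
            cz = z1 - z0
            span = (cz - 1) * plane + (H - 1) * Wp + Wd
            base = z0 * plane
            for k, off in enumerate(offs):
                col[k * self.cin : (k + 1) * self.cin, :span] = xpf[
                    :, base + off : base + off + span
                ]
            g_flat = g_flat_all[:, base : base + span]
            gW += g_flat @ col[:, :span].T
            gcol = Wm.T @ g_flat
            for k, off in enumerate(offs):
                gxpf[:, base + off : base + off + span] += gcol[
                    k * self.cin : (k + 1) * self.cin
                ]
        self.W.grad += gW
        gx = gxp[:, pz : pz + D, py : py + H, px : px + Wd]
        return np.ascontiguousarray(gx)


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial axes with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self._cache: Optional[Tuple] = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv_std
        out = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        self._cache = (xhat, inv_std, x.shape)
        return out.reshape(x.shape).astype(x.dtype, copy=False)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        c = shape[0]
        g = gout.reshape(c, -1)
        n = g.shape[1]
        self.gamma.grad += (g * xhat).sum(axis=1)
        self.beta.grad += g.sum(axis=1)
        gxhat = g * self.gamma.value[:, None]
        gx = (
            inv_std
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=1, keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=1, keepdims=True)
            )
        )
        return gx.reshape(shape).astype(gout.dtype, copy=False)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, self.slope * gout)


class AvgPool2(Layer):
    """2x2x2 average pooling with stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {x.shape[1:]}")
        self._in_shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout / 8.0
        for ax in (1, 2, 3):
            g = np.repeat(g, 2, axis=ax)
        return g.astype(gout.dtype, copy=False)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling along all spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for ax in (1, 2, 3):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, d, h, w = gout.shape
        return gout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-2,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over axis 0 (the class/channel axis)."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)
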