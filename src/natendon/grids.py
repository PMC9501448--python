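"""Helpers for aligned fine/coarse voxel grids.

The proton grid (1 mm) and the sodium grid (2 mm) share the field of view and
origin; the coarse voxel size must be an integer multiple of the fine one, so
every coarse voxel tiles an integer block of fine voxels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["downsample_factors", "block_mean", "block_fraction"]


def downsample_factors(fine_voxel_mm, coarse_voxel_mm) -> tuple[int, int, int]:
    """Per-axis integer downsampling factors between two aligned grids."""
    fine = np.broadcast_to(np.asarray(fine_voxel_mm, dtype=float).reshape(-1), (3,)) \
        if np.asarray(fine_voxel_mm).size in (1, 3) else None
    if fine is None:
        raise ValueError("fine_voxel_mm must be scalar or 3-vector")
    coarse = np.broadcast_to(np.asarray(coarse_voxel_mm, dtype=float).reshape(-1), (3,)) \
        if np.asarray(coarse_voxel_mm).size in (1, 3) else None
    if coarse is None:
        raise ValueError("coarse_voxel_mm must be scalar or 3-vector")
    ratio = coarse / fine
    factors = np.round(ratio).astype(int)
    if np.any(factors < 1) or not np.allclose(ratio, factors, atol=1e-6):
        raise ValueError(
            f"coarse voxel {coarse.tolist()} mm is not an integer multiple of fine voxel {fine.tolist()} mm"
        )
    return tuple(int(f) for f in factors)


def block_mean(arr: np.ndarray, factors) -> np.ndarray:
    """Mean over non-overlapping blocks of shape ``factors``.

    The array shape must be divisible by the factors along each axis.
    """
    arr = np.asarray(arr, dtype=float)
    if np.isscalar(factors) or np.asarray(factors).size == 1:
        factors = (int(factors),) * 3
    fx, fy, fz = (int(f) for f in factors)
    sx, sy, sz = arr.shape
    if sx % fx or sy % fy or sz % fz:
        raise ValueError(f"array shape {arr.shape} not divisible by block factors {(fx, fy, fz)}")
    return arr.reshape(sx // fx, fx, sy // fy, fy, sz // fz, fz).mean(axis=(1, 3, 5))


def block_fraction(mask: np.ndarray, factors) -> np.ndarray:
    """Per-block fraction of True voxels in a boolean mask."""
    return block_mean(np.asarray(mask, dtype=float), factors)
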