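"""Region-of-interest tools: tendon segmentation and cross-resolution transfer.

The tendon mask is divided along the slice axis into three consecutive 3-cm
segments starting at the calcaneal (distal, lowest slice index) end: INS, MID,
MTJ.  Masks drawn on the proton grid are transferred to the coarser sodium
grid by voxel-fraction counting.
"""

from __future__ import annotations

import numpy as np

from .datamodel import LabelMap, Role, SEGMENT_ROLES
from .grids import block_fraction, downsample_factors

__all__ = ["segment_tendon_mask", "transfer_mask", "label_fractions"]


def segment_tendon_mask(
    fine_mask: LabelMap,
    tendon_code: int = Role.TENDON,
    segment_length_mm: float = 30.0,
) -> LabelMap:
    """Partition a single-code tendon mask into INS/MID/MTJ along the slice axis.

    Slices are assigned by distance from the most distal occupied slice in
    half-open
    ``[0, L)``, ``[L, 2L)``, ``[2L, 3L)`` mm runs with ``L = segment_length_mm``;
    more proximal slices stay unlabeled.  Voxels of other codes are untouched.
    Raises ``ValueError`` when the tendon spans less than three segments.
    """
    tendon = fine_mask.mask(tendon_code)
    occupied = np.flatnonzero(tendon.any(axis=(0, 1)))
    if occupied.size == 0:
        raise ValueError(f"no voxels with tendon code {int(tendon_code)} in mask")
    dz = float(fine_mask.voxel_size_mm[2])
    z0 = int(occupied[0])
    extent_mm = (int(occupied[-1]) - z0 + 1) * dz
    if extent_mm < 3 * segment_length_mm - 1e-9:
        raise ValueError(
            f"tendon length {extent_mm:g} mm < {3 * segment_length_mm:g} mm "
            "(three segments required)"
        )
    labels = fine_mask.labels.copy()
    labels[tendon] = 0
    nz = labels.shape[2]
    z = np.arange(nz)
    seg_index = np.floor((z - z0) * dz / segment_length_mm).astype(int)
    for k, role in enumerate(SEGMENT_ROLES):
        in_run = (seg_index == k) & (z >= z0)
        sel = tendon & in_run[None, None, :]
        labels[sel] = int(role)
    legend = {int(k): v for k, v in fine_mask.legend.items() if int(k) != int(tendon_code)}
    for role in SEGMENT_ROLES:
        legend[int(role)] = role.name
    return LabelMap(labels, fine_mask.voxel_size_mm, fine_mask.origin_mm, legend)


def label_fractions(fine_mask: LabelMap, coarse_voxel_mm) -> dict[int, np.ndarray]:
    """Per-coarse-voxel coverage fraction of every nonzero label code."""
    factors = downsample_factors(fine_mask.voxel_size_mm, coarse_voxel_mm)
    codes = sorted(set(np.unique(fine_mask.labels).tolist()) - {0})
    return {int(c): block_fraction(fine_mask.labels == c, factors) for c in codes}


def transfer_mask(
    fine_mask: LabelMap,
    coarse_voxel_mm,
    inclusion_threshold: float = 0.5,
) -> LabelMap:
    """Transfer a fine-grid label map to an aligned coarser grid.

    Each coarse voxel takes the code with the largest fine-voxel coverage
    fraction, provided that fraction reaches ``inclusion_threshold``
    (inclusive).  Fraction ties resolve to the smaller code, which for the
    tendon segments means the more distal one (INS < MID < MTJ).
    """
    fractions = label_fractions(fine_mask, coarse_voxel_mm)
    factors = downsample_factors(fine_mask.voxel_size_mm, coarse_voxel_mm)
    coarse_shape = tuple(s // f for s, f in zip(fine_mask.shape, factors))
    labels = np.zeros(coarse_shape, dtype=np.int32)
    if fractions:
        codes = np.array(sorted(fractions), dtype=np.int32)
        stack = np.stack([fractions[int(c)] for c in codes], axis=0)
        best = np.argmax(stack, axis=0)  # first max -> smallest code on ties
        best_frac = np.take_along_axis(stack, best[None], axis=0)[0]
        include = best_frac >= inclusion_threshold - 1e-12
        labels[include] = codes[best[include]]
    coarse_voxel = np.broadcast_to(np.asarray(coarse_voxel_mm, dtype=float).reshape(-1), (3,))
    legend = {c: fine_mask.legend[c] for c in np.unique(labels).tolist() if c != 0}
    return LabelMap(labels, coarse_voxel.copy(), fine_mask.origin_mm, legend)
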