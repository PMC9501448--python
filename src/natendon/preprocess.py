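"""Coil-sensitivity estimation/correction and translation-only registration.

A surface coil receives with spatially falling sensitivity; a scan of a
homogeneous 154 mM phantom maps that field.  The scan is smoothed, normalized
to its maximum, and used as a voxel-wise divisor.  Motion between the long
acquisitions is modelled as integer-voxel translation recovered by maximizing
normalized cross-correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .datamodel import Volume3D, same_grid

__all__ = [
    "SensitivityMap",
    "estimate_sensitivity_map",
    "apply_sensitivity_correction",
    "register_translation",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SensitivityMap:
    """Normalized coil reception field in [0, 1] with a validity mask.

    Voxels below ``validity_fraction`` of the maximum are unreliable divisors
    and are excluded from downstream ROI statistics.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray
    normalization_reference: str = "maximum of smoothed homogeneous-phantom scan"

    @property
    def shape(self):
        return self.values.shape


def estimate_sensitivity_map(
    homogeneous_scan: Volume3D,
    smoothing_fwhm_mm: float = 6.0,
    validity_fraction: float = 0.05,
) -> SensitivityMap:
    """Estimate the coil sensitivity field from a homogeneous-phantom scan.

    The scan is Gaussian-smoothed (FWHM in mm), divided by its maximum, and
    voxels below ``validity_fraction`` of the maximum are marked invalid.
    """
    data = homogeneous_scan.data
    if np.all(data == 0):
        raise ValueError("sensitivity scan is all zeros")
    sigma_vox = smoothing_fwhm_mm * _FWHM_TO_SIGMA / homogeneous_scan.voxel_size_mm
    smoothed = gaussian_filter(data, sigma=tuple(sigma_vox), mode="nearest")
    peak = float(smoothed.max())
    if peak <= 0:
        raise ValueError("sensitivity scan has non-positive maximum after smoothing")
    values = np.clip(smoothed / peak, 0.0, 1.0)
    valid = values >= validity_fraction
    values = np.where(valid, values, 0.0)
    return SensitivityMap(
        values=values,
        valid_mask=valid,
        voxel_size_mm=homogeneous_scan.voxel_size_mm.copy(),
        origin_mm=homogeneous_scan.origin_mm.copy(),
    )


def apply_sensitivity_correction(
    volume: Volume3D, smap: SensitivityMap
) -> tuple[Volume3D, np.ndarray]:
    """Divide a volume by the sensitivity field on valid voxels.

    Returns the corrected volume and the validity mask; invalid voxels are set
    to zero and must be excluded from ROI statistics by the caller (ROI
    helpers accept the mask).
    """
    if volume.shape != smap.shape or not np.allclose(
        volume.voxel_size_mm, smap.voxel_size_mm, atol=1e-6
    ):
        raise ValueError("volume and sensitivity map are on different grids")
    corrected = np.zeros_like(volume.data)
    np.divide(volume.data, smap.values, out=corrected, where=smap.valid_mask)
    return volume.copy_with(corrected), smap.valid_mask.copy()


@dataclass
class RegistrationResult:
    """Recovered integer shift, aligned volume, NCC score and edge validity."""

    shift: tuple
    resampled: Volume3D
    correlation: float
    valid_mask: np.ndarray


def register_translation(
    moving: Volume3D,
    fixed: Volume3D,
    max_shift_voxels: int = 3,
) -> RegistrationResult:
    """Recover an integer-voxel shift by exhaustive NCC search.

    Searches shifts in ``[-max_shift, max_shift]^3``; the shift that maximizes
    the normalized cross-correlation between ``roll(moving, -shift)`` and
    ``fixed`` wins.  Ties break to the smallest shift magnitude, then
    lexicographically.  ``shift`` is the displacement that was applied to the
    moving volume; the resample rolls it back, and voxels wrapped across an
    edge are marked invalid in ``valid_mask``.  A best correlation below 0.1
    triggers a warning (featureless images).
    """
    if not same_grid(moving, fixed):
        raise ValueError("moving and fixed volumes are on different grids")
    m = int(max_shift_voxels)
    if any(2 * m + 1 > s for s in moving.shape):
        raise ValueError(f"search window +-{m} exceeds grid {moving.shape}")
    candidates = sorted(
        itertools.product(range(-m, m + 1), repeat=3),
        key=lambda s: (sum(c * c for c in s), s),
    )
    # Shifts are circular rolls, so the NCC of every candidate comes from one
    # circular cross-correlation (FFT); normalization is shift-invariant.
    a = moving.data - moving.data.mean()
    b = fixed.data - fixed.data.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    cc = np.fft.irfftn(
        np.conj(np.fft.rfftn(a)) * np.fft.rfftn(b), s=a.shape, axes=(0, 1, 2)
    )  # cc[s] = sum_x a(x) * b(x + s), so NCC at a candidate shift is cc[-shift]
    best_shift, best_corr = (0, 0, 0), -np.inf
    for shift in candidates:
        idx = tuple((-c) % n for c, n in zip(shift, a.shape))
        corr = float(cc[idx]) / denom if denom > 0 else 0.0
        if corr > best_corr + 1e-12:
            best_corr, best_shift = corr, shift
    if best_corr < 0.1:
        warnings.warn(
            f"registration correlation {best_corr:.3f} is near zero; shift unreliable",
            stacklevel=2,
        )
    back = tuple(-c for c in best_shift)
    resampled = moving.copy_with(np.roll(moving.data, back, axis=(0, 1, 2)))
    valid = np.ones(moving.shape, dtype=bool)
    for axis, b in enumerate(back):
        if b > 0:
            index = [slice(None)] * 3
            index[axis] = slice(0, b)
            valid[tuple(index)] = False
        elif b < 0:
            index = [slice(None)] * 3
            index[axis] = slice(moving.shape[axis] + b, None)
            valid[tuple(index)] = False
    return RegistrationResult(tuple(best_shift), resampled, best_corr, valid)
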