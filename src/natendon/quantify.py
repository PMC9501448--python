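"""SNR and apparent tissue sodium concentration (aTSC).

The concentration-weighted sodium image is converted to concentration through
a straight-line calibration over the reference vials, then corrected for (a)
the different relaxation weighting of tendon tissue versus agarose vials at
the chosen TR/TE and (b) partial-volume signal dilution in the coarse sodium
voxels, quantified by counting fine-grid tendon voxels inside each sodium
voxel:

    aTSC_raw  = (S - intercept) / slope
    aTSC_corr = aTSC_raw * f_phantom / f_tissue / mean_fraction

with the relaxation weighting factor
``f = (1 - exp(-TR/T1)) * (ps * exp(-TE/T2s*) + (1-ps) * exp(-TE/T2l*))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datamodel import LabelMap, RelaxationParams, Volume3D, same_grid
from .grids import block_fraction, downsample_factors

__all__ = [
    "ROIStats",
    "CalibrationLine",
    "PartialVolume",
    "QuantResult",
    "roi_stats",
    "compute_snr",
    "fit_calibration",
    "relaxation_weighting_factor",
    "partial_volume_fraction",
    "compute_atsc",
]


@dataclass(frozen=True)
class ROIStats:
    """Mean, unbiased SD, relative SD in % and voxel count of one ROI."""

    mean: float
    sd: float
    rel_sd_pct: float
    n_voxels: int


def roi_stats(values: np.ndarray) -> ROIStats:
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 1:
        raise ValueError("ROI is empty")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    rel = 100.0 * sd / abs(mean) if mean != 0 else np.inf if sd > 0 else 0.0
    return ROIStats(mean=mean, sd=sd, rel_sd_pct=rel, n_voxels=int(values.size))


def compute_snr(
    volume: Volume3D,
    roi: LabelMap,
    roi_code: int,
    noise: LabelMap,
    noise_code: int,
    min_noise_voxels: int = 100,
    valid: np.ndarray | None = None,
) -> ROIStats:
    """Per-voxel SNR over an ROI: voxel value / SD of the noise ROI.

    The noise SD uses the unbiased (n-1) estimator over a dedicated
    signal-free region; ``valid`` optionally excludes ROI voxels.
    """
    if not same_grid(volume, roi) or not same_grid(volume, noise):
        raise ValueError("volume and ROI maps are on different grids")
    noise_values = volume.data[noise.mask(noise_code)]
    if noise_values.size < max(min_noise_voxels, 2):
        raise ValueError(
            f"noise ROI has {noise_values.size} voxels, need >= {max(min_noise_voxels, 2)}"
        )
    noise_sd = float(noise_values.std(ddof=1))
    if noise_sd == 0:
        raise ValueError("noise ROI has zero standard deviation")
    roi_mask = roi.mask(roi_code)
    if valid is not None:
        roi_mask = roi_mask & valid
    if not roi_mask.any():
        raise ValueError("signal ROI is empty")
    return roi_stats(volume.data[roi_mask] / noise_sd)


@dataclass(frozen=True)
class CalibrationLine:
    """Straight-line fit of vial ROI-mean signal versus concentration."""

    slope: float           # a.u. per mM
    intercept: float       # a.u.
    r_squared: float
    concentrations_mM: tuple
    vial_means: tuple

    def invert(self, signal) -> np.ndarray | float:
        """Signal (a.u.) -> concentration (mM)."""
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope:g}")
        return (signal - self.intercept) / self.slope


def fit_calibration(vial_means: Sequence[float], concentrations_mM: Sequence[float]) -> CalibrationLine:
    """Ordinary least squares of vial means against concentrations."""
    y = np.asarray(vial_means, dtype=float).ravel()
    x = np.asarray(concentrations_mM, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("one mean per concentration required")
    if x.size < 2:
        raise ValueError("need at least 2 vials for calibration")
    if np.unique(x).size < 2:
        raise ValueError("vial concentrations must be distinct")
    fit = sps.linregress(x, y)
    return CalibrationLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        concentrations_mM=tuple(float(c) for c in x),
        vial_means=tuple(float(v) for v in y),
    )


def relaxation_weighting_factor(
    relaxation: RelaxationParams, tr_ms: float, te_ms: float
) -> float:
    """Fraction of the fully relaxed signal observed at a given TR/TE.

    Strictly increasing in TR (saturation recovery) and strictly decreasing
    in TE (biexponential decay); bounded in (0, 1].
    """
    if not isinstance(relaxation, RelaxationParams):
        relaxation = RelaxationParams(*relaxation)
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if te_ms < 0:
        raise ValueError("te_ms must be non-negative")
    r = relaxation
    return float(
        (1.0 - np.exp(-tr_ms / r.t1_ms))
        * (r.ps * np.exp(-te_ms / r.t2s_ms) + (1.0 - r.ps) * np.exp(-te_ms / r.t2l_ms))
    )


@dataclass
class PartialVolume:
    """Per-coarse-voxel tissue coverage and its ROI mean."""

    mean_fraction: float
    roi_mask: np.ndarray       # coarse boolean ROI (fraction >= threshold)
    fractions: np.ndarray      # coarse fraction field in [0, 1]
    inclusion_threshold: float


def partial_volume_fraction(
    fine_mask: LabelMap,
    code,
    coarse_voxel_mm,
    inclusion_threshold: float = 0.5,
    roi_mask: np.ndarray | None = None,
) -> PartialVolume:
    """Count fine-grid tissue voxels inside each coarse voxel.

    ``code`` may be one label code or a sequence (the union is counted, used
    for the whole-tendon ROI).  The coarse ROI consists of voxels whose
    fraction reaches the inclusion threshold; the mean fraction is averaged
    over that ROI.  ``roi_mask`` overrides the thresholded ROI with an
    explicit coarse boolean mask — the partial-volume correction is unbiased
    only when the fraction is averaged over the same voxels as the signal, so
    callers that derive the region mask differently (e.g. by competitive
    label transfer) should pass it here.
    """
    factors = downsample_factors(fine_mask.voxel_size_mm, coarse_voxel_mm)
    codes = [code] if np.isscalar(code) else list(code)
    union = np.zeros(fine_mask.shape, dtype=bool)
    for c in codes:
        union |= fine_mask.mask(c)
    fractions = block_fraction(union, factors)
    if roi_mask is not None:
        roi = np.asarray(roi_mask, dtype=bool)
        if roi.shape != fractions.shape:
            raise ValueError("roi_mask is not on the coarse grid")
    else:
        roi = fractions >= inclusion_threshold - 1e-12
    if not roi.any():
        raise ValueError("coarse ROI is empty at this inclusion threshold")
    return PartialVolume(
        mean_fraction=float(fractions[roi].mean()),
        roi_mask=roi,
        fractions=fractions,
        inclusion_threshold=float(inclusion_threshold),
    )


@dataclass
class QuantResult:
    """Per-region quantification summary of one subject.

    ``atsc``, ``snr`` and ``h1_t2star`` map region name (INS/MID/MTJ/Total)
    to :class:`ROIStats`; ``Total`` is the union of the three segments.
    ``factors`` records the relaxation weighting factors used and ``qc``
    counts negative-concentration voxels (noise can push voxels below zero).
    """

    atsc: dict = field(default_factory=dict)
    snr: dict = field(default_factory=dict)
    h1_t2star: dict = field(default_factory=dict)
    calibration: CalibrationLine | None = None
    mean_fractions: dict = field(default_factory=dict)
    factors: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)


def compute_atsc(
    volume: Volume3D,
    coarse_labels: LabelMap,
    calibration: CalibrationLine,
    tissue_relaxation: Mapping[str, RelaxationParams],
    phantom_relaxation: RelaxationParams,
    partial_volumes: Mapping[str, PartialVolume],
    regions: Sequence[str] = ("INS", "MID", "MTJ"),
    valid: np.ndarray | None = None,
) -> QuantResult:
    """Assemble aTSC per region and for the whole tendon.

    ``volume`` is the sensitivity-corrected concentration-weighted sodium
    image; ``coarse_labels`` carries the region codes on the same grid;
    ``partial_volumes`` must contain every region and ``"Total"``.
    TR/TE are taken from the volume metadata for the relaxation factors.
    """
    if calibration.slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {calibration.slope:g}")
    if not same_grid(volume, coarse_labels):
        raise ValueError("volume and label map are on different grids")
    if volume.tr_ms is None or volume.te_ms is None:
        raise ValueError("volume must carry TR/TE metadata for relaxation correction")
    missing = [r for r in list(regions) + ["Total"] if r not in tissue_relaxation]
    if missing:
        raise ValueError(f"missing tissue relaxation parameters for regions: {missing}")
    f_phantom = relaxation_weighting_factor(phantom_relaxation, volume.tr_ms, volume.te_ms)
    code_of = {v: k for k, v in coarse_labels.legend.items()}
    result = QuantResult(calibration=calibration)
    result.factors["phantom"] = f_phantom
    total_mask = np.zeros(volume.shape, dtype=bool)
    qc_negative = {}
    for region in regions:
        if region not in code_of:
            raise ValueError(f"region {region} absent from label map legend")
        mask = coarse_labels.mask(code_of[region])
        if valid is not None:
            mask = mask & valid
        total_mask |= mask
        pv = partial_volumes[region]
        f_tissue = relaxation_weighting_factor(tissue_relaxation[region], volume.tr_ms, volume.te_ms)
        atsc = calibration.invert(volume.data[mask]) * (f_phantom / f_tissue) / pv.mean_fraction
        result.atsc[region] = roi_stats(atsc)
        result.factors[region] = f_tissue
        result.mean_fractions[region] = pv.mean_fraction
        qc_negative[region] = int((atsc < 0).sum())
    if not total_mask.any():
        raise ValueError("whole-tendon ROI is empty")
    pv_total = partial_volumes["Total"]
    f_total = relaxation_weighting_factor(tissue_relaxation["Total"], volume.tr_ms, volume.te_ms)
    atsc_total = (
        calibration.invert(volume.data[total_mask]) * (f_phantom / f_total) / pv_total.mean_fraction
    )
    result.atsc["Total"] = roi_stats(atsc_total)
    result.factors["Total"] = f_total
    result.mean_fractions["Total"] = pv_total.mean_fraction
    qc_negative["Total"] = int((atsc_total < 0).sum())
    result.qc["negative_voxels"] = qc_negative
    return result
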