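"""Digital phantom generator for synthetic sodium-MRI tendon studies.

The generator emulates, in image space, the surface-coil acquisitions the
analysis pipeline consumes: a tendon-like tube and four agarose-like reference
vials on a 1-mm proton grid, rendered with saturation-recovery / biexponential
relaxation weighting

    S = scale * C * (1 - exp(-TR/T1)) * (ps * exp(-TE/T2s*) + (1-ps) * exp(-TE/T2l*)),

multiplied by a coil-sensitivity field, downsampled to the 2-mm sodium grid,
and degraded with additive noise.  Every stage of the analysis can be checked
against the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .datamodel import (
    LabelMap,
    Nucleus,
    PHANTOM_RELAXATION,
    RelaxationParams,
    Role,
    SEGMENT_ROLES,
    StudyConfig,
    TENDON_RELAXATION,
    VIAL_ROLES,
    Volume3D,
)
from .grids import block_mean, downsample_factors
from .roi import transfer_mask

__all__ = [
    "CompartmentSpec",
    "PhantomSpec",
    "GroundTruth",
    "StudyBundle",
    "Phantom",
    "ideal_signal",
    "render_acquisition",
    "generate_study",
    "default_compartments",
    "regional_tendon_compartments",
    "cohort_spec",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Relaxation surrogate for the 154 mM homogeneous water phantom of the
#: coil-sensitivity scan (free sodium: long T1, effectively monoexponential T2*).
WATER_RELAXATION = RelaxationParams(t1_ms=56.0, t2s_ms=55.0, t2l_ms=55.0, ps=0.5)


def ideal_signal(
    concentration_mM: float,
    relaxation: RelaxationParams,
    tr_ms: float,
    te_ms: float,
    scale: float = 1.0,
) -> float:
    """Noise-free relaxation-weighted signal of a compartment (a.u.).

    Saturation-recovery longitudinal weighting times biexponential transverse
    decay, with amplitude proportional to sodium concentration.
    """
    if not isinstance(relaxation, RelaxationParams):
        relaxation = RelaxationParams(*relaxation)
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if te_ms < 0:
        raise ValueError("te_ms must be non-negative")
    if concentration_mM < 0:
        raise ValueError("concentration must be non-negative")
    r = relaxation
    longitudinal = 1.0 - np.exp(-tr_ms / r.t1_ms)
    transverse = r.ps * np.exp(-te_ms / r.t2s_ms) + (1.0 - r.ps) * np.exp(-te_ms / r.t2l_ms)
    return float(scale * concentration_mM * longitudinal * transverse)


@dataclass(frozen=True)
class CompartmentSpec:
    """One labelled compartment of the digital phantom.

    ``shape`` is ``"cylinder"`` (axis along the slice axis; ``size_mm`` =
    (radius, radius, length)) or ``"box"`` (``size_mm`` = full edge lengths).
    A fine voxel belongs to the compartment when its centre falls inside the
    geometry.  The proton side of the compartment is described by a
    monoexponential T2* and an amplitude in a.u.
    """

    role: Role
    center_mm: tuple
    shape: str = "cylinder"
    size_mm: tuple = (5.0, 5.0, 35.0)
    concentration_mM: float = 0.0
    relaxation: RelaxationParams = PHANTOM_RELAXATION
    h1_t2star_ms: float = 10.0
    h1_amplitude: float = 0.0

    def __post_init__(self):
        if self.shape not in ("cylinder", "box"):
            raise ValueError(f"unknown compartment shape {self.shape!r}")
        if self.concentration_mM < 0 or not np.isfinite(self.concentration_mM):
            raise ValueError("concentration must be finite and non-negative")

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Membership of world points (broadcastable mm coordinates)."""
        cx, cy, cz = (float(c) for c in self.center_mm)
        if self.shape == "cylinder":
            r, _, length = (float(s) for s in self.size_mm)
            return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (np.abs(z - cz) <= length / 2.0)
        hx, hy, hz = (float(s) / 2.0 for s in self.size_mm)
        return (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)


def default_compartments(
    tendon_concentration_mM: float = 82.2,
    tendon_relaxation: RelaxationParams = TENDON_RELAXATION["Total"],
    vial_concentrations_mM: Sequence[float] = (50.0, 75.0, 100.0, 125.0),
    include_skin: bool = False,
    fov_mm: Sequence[float] = (180.0, 180.0, 180.0),
) -> tuple[CompartmentSpec, ...]:
    """Study-like layout: one tendon tube, four vials, one noise box.

    The tendon is a 95-mm tube (radius 5 mm) along the slice axis so that the
    three 30-mm segments fit with a small proximal remainder; vials (radius
    5 mm, height 35 mm) sit behind the tendon plane; the noise box is a
    signal-free 30-mm cube within the field of view.
    """
    fx, fy, fz = (float(v) for v in fov_mm)
    tendon_z0 = 20.0
    comps = [
        CompartmentSpec(
            role=Role.TENDON,
            center_mm=(fx / 2.0, fy * 0.3, tendon_z0 + 47.5),
            shape="cylinder",
            size_mm=(5.0, 5.0, 95.0),
            concentration_mM=tendon_concentration_mM,
            relaxation=tendon_relaxation,
            h1_t2star_ms=2.1,
            h1_amplitude=100.0,
        )
    ]
    vial_x = np.linspace(0.2, 0.8, 4) * fx
    for role, conc, x in zip(VIAL_ROLES, vial_concentrations_mM, vial_x):
        comps.append(
            CompartmentSpec(
                role=role,
                center_mm=(float(x), fy * 0.8, fz / 2.0),
                shape="cylinder",
                size_mm=(5.0, 5.0, 35.0),
                concentration_mM=float(conc),
                relaxation=PHANTOM_RELAXATION,
                h1_t2star_ms=10.0,
                h1_amplitude=120.0,
            )
        )
    noise_edge = min(30.0, 0.25 * min(fx, fy))  # keep clear of the tendon lane
    comps.append(
        CompartmentSpec(
            role=Role.NOISE,
            center_mm=(1.0 + noise_edge / 2.0, 1.0 + noise_edge / 2.0, fz / 2.0),
            shape="box",
            size_mm=(noise_edge, noise_edge, noise_edge),
            concentration_mM=0.0,
            h1_amplitude=0.0,
        )
    )
    if include_skin:
        comps.append(
            CompartmentSpec(
                role=Role.SKIN,
                center_mm=(fx / 2.0, fy * 0.3 - 7.0, tendon_z0 + 47.5),
                shape="box",
                size_mm=(14.0, 3.0, 95.0),
                concentration_mM=45.0,
                relaxation=RelaxationParams(30.0, 4.0, 14.0, 0.5),
                h1_t2star_ms=8.0,
                h1_amplitude=150.0,
            )
        )
    return tuple(comps)


def regional_tendon_compartments(
    concentrations_mM: Mapping[str, float] | None = None,
    relaxations: Mapping[str, RelaxationParams] | None = None,
    **kwargs,
) -> tuple[CompartmentSpec, ...]:
    """Layout with the tendon split into INS/MID/MTJ compartments.

    Defaults use the reported healthy-control regional aTSC means
    (INS 112.9, MID 77.3, MTJ 55.3 mM) and regional relaxation values, so a
    synthetic cohort reproduces the distal-to-proximal concentration gradient.
    """
    conc = {"INS": 112.9, "MID": 77.3, "MTJ": 55.3}
    if concentrations_mM:
        conc.update(concentrations_mM)
    relax = dict(TENDON_RELAXATION)
    if relaxations:
        relax.update(relaxations)
    base = default_compartments(**kwargs)
    out = []
    for comp in base:
        if comp.role is not Role.TENDON:
            out.append(comp)
            continue
        cx, cy, cz = comp.center_mm
        _, _, length = comp.size_mm
        z0 = cz - length / 2.0
        for k, role in enumerate(SEGMENT_ROLES):
            seg_len = 30.0 if k < 2 else length - 60.0
            out.append(
                dataclasses.replace(
                    comp,
                    role=role,
                    center_mm=(cx, cy, z0 + 30.0 * k + seg_len / 2.0),
                    size_mm=(comp.size_mm[0], comp.size_mm[1], seg_len),
                    concentration_mM=conc[role.name],
                    relaxation=relax[role.name],
                )
            )
    return tuple(out)


@dataclass
class PhantomSpec:
    """Full description of a synthetic study.

    ``target_snr`` (when set) overrides ``noise_sigma``: the noise standard
    deviation is chosen so that (mean noise-free concentration-weighted tendon
    signal over the coarse tendon ROI) / sigma equals the target.
    """

    fov_mm: tuple = (180.0, 180.0, 180.0)
    fine_voxel_mm: float = 1.0
    coarse_voxel_mm: float = 2.0
    compartments: tuple = field(default_factory=default_compartments)
    scale_au_per_mM: float = 1.0
    sensitivity_model: str = "uniform"  # or "exp_falloff"
    sensitivity_depth_mm: float = 80.0
    noise_sigma: float = 0.0
    target_snr: float | None = None
    h1_noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    psf_mode: str = "block_average"  # or "gaussian_psf"
    psf_fwhm_mm: float = 3.0
    shift_voxels: Mapping[str, tuple] = field(default_factory=dict)
    roi_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.fov_mm = tuple(float(v) for v in self.fov_mm)
        if self.noise_sigma < 0 or self.h1_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.sensitivity_model not in ("uniform", "exp_falloff"):
            raise ValueError(f"unknown sensitivity model {self.sensitivity_model!r}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.psf_mode not in ("block_average", "gaussian_psf"):
            raise ValueError(f"unknown psf mode {self.psf_mode!r}")
        downsample_factors(self.fine_voxel_mm, self.coarse_voxel_mm)
        roles = [c.role for c in self.compartments]
        if len(set(roles)) != len(roles):
            raise ValueError("compartment roles must be unique")


@dataclass
class GroundTruth:
    """True values every analysis stage should recover."""

    concentrations_mM: dict
    relaxations: dict
    fractions: dict          # role name -> per-coarse-voxel coverage fraction
    noise_sigma: float
    true_snr: float | None
    scale_au_per_mM: float
    tendon_roles: tuple

    def to_jsonable(self) -> dict:
        return {
            "concentrations_mM": self.concentrations_mM,
            "relaxations": {
                k: dataclasses.asdict(v) for k, v in self.relaxations.items()
            },
            "mean_fractions": {
                k: float(v[v > 0].mean()) if np.any(v > 0) else 0.0
                for k, v in self.fractions.items()
            },
            "noise_sigma": self.noise_sigma,
            "true_snr": self.true_snr,
            "scale_au_per_mM": self.scale_au_per_mM,
            "tendon_roles": [str(r) for r in self.tendon_roles],
        }


class Phantom:
    """Pre-rasterized phantom: compartment masks, sensitivity field, fractions.

    Rasterizing once makes repeated renders (protocol series, seed sweeps)
    cheap: each acquisition is a weighted sum of cached boolean masks.
    """

    def __init__(self, spec: PhantomSpec, config: StudyConfig | None = None):
        self.spec = spec
        self.config = config or StudyConfig()
        self.factors = downsample_factors(spec.fine_voxel_mm, spec.coarse_voxel_mm)
        h = float(spec.fine_voxel_mm)
        self.fine_shape = tuple(int(round(f / h)) for f in spec.fov_mm)
        for dim, fac in zip(self.fine_shape, self.factors):
            if dim % fac:
                raise ValueError("field of view does not tile the coarse grid")
        self.coarse_shape = tuple(s // f for s, f in zip(self.fine_shape, self.factors))
        # voxel-centre world coordinates
        xs = (np.arange(self.fine_shape[0]) + 0.5) * h
        ys = (np.arange(self.fine_shape[1]) + 0.5) * h
        zs = (np.arange(self.fine_shape[2]) + 0.5) * h
        X = xs[:, None, None]
        Y = ys[None, :, None]
        Z = zs[None, None, :]
        for comp in spec.compartments:
            c = np.asarray(comp.center_mm, dtype=float)
            if comp.shape == "cylinder":
                half = np.array([comp.size_mm[0], comp.size_mm[1], comp.size_mm[2] / 2.0])
            else:
                half = np.asarray(comp.size_mm, dtype=float) / 2.0
            if np.any(c - half < -1e-9) or np.any(c + half > np.asarray(spec.fov_mm) + 1e-9):
                raise ValueError(
                    f"compartment {comp.role.name} does not fit inside the field of view "
                    f"{spec.fov_mm} mm"
                )
        labels = np.zeros(self.fine_shape, dtype=np.int32)
        self.masks: dict[Role, np.ndarray] = {}
        for comp in spec.compartments:
            inside = comp.contains(X, Y, Z)
            labels[inside] = int(comp.role)
        for comp in spec.compartments:
            self.masks[comp.role] = labels == int(comp.role)
        legend = {int(c.role): c.role.name for c in spec.compartments}
        self.fine_mask = LabelMap(labels, np.full(3, h), np.zeros(3), legend)
        self.coarse_mask = transfer_mask(
            self.fine_mask, spec.coarse_voxel_mm, inclusion_threshold=spec.roi_threshold
        )
        # Sensitivity field: exponential falloff from the coil plane (min
        # slice-axis face), sampled at coarse-voxel centres and held constant
        # within each sodium voxel so that voxel-wise division by the coarse
        # map inverts the attenuation exactly.
        if spec.sensitivity_model == "uniform":
            self.sensitivity_coarse = np.ones(self.coarse_shape)
            self.sensitivity_fine = np.ones(self.fine_shape)
        else:
            hc = float(spec.coarse_voxel_mm)
            depth_c = (np.arange(self.coarse_shape[2]) + 0.5) * hc
            profile = np.exp(-depth_c / spec.sensitivity_depth_mm)
            self.sensitivity_coarse = np.broadcast_to(
                profile[None, None, :], self.coarse_shape
            ).copy()
            fine = self.sensitivity_coarse
            for axis, f in enumerate(self.factors):
                fine = np.repeat(fine, f, axis=axis)
            self.sensitivity_fine = fine
        self.fractions = {
            comp.role.name: block_mean(self.masks[comp.role].astype(float), self.factors)
            for comp in spec.compartments
        }
        self.tendon_roles = tuple(
            c.role for c in spec.compartments if c.role in (Role.TENDON,) + tuple(SEGMENT_ROLES)
        )
        self.noise_sigma = float(spec.noise_sigma)
        self.true_snr = spec.target_snr
        if spec.target_snr is not None:
            mean_sig = self._tendon_roi_mean_ideal()
            self.noise_sigma = mean_sig / float(spec.target_snr)
        elif self.noise_sigma > 0:
            self.true_snr = self._tendon_roi_mean_ideal() / self.noise_sigma

    def _tendon_roi_mean_ideal(self) -> float:
        """Noise-free concentration-weighted signal averaged over the coarse tendon ROI."""
        cfg = self.config
        coarse = self._render_coarse_ideal(Nucleus.NA23, cfg.quant_tr_ms, cfg.quant_te_ms)
        roi = np.zeros(self.coarse_shape, dtype=bool)
        for role in self.tendon_roles:
            roi |= self.coarse_mask.labels == int(role)
        if not roi.any():
            raise ValueError("no coarse tendon ROI voxels; cannot define true SNR")
        return float(coarse[roi].mean())

    def _fine_ideal(
        self, nucleus: Nucleus, tr_ms: float, te_ms: float, overrides=None
    ) -> np.ndarray:
        out = np.zeros(self.fine_shape)
        overrides = overrides or {}
        for comp in self.spec.compartments:
            if nucleus is Nucleus.NA23:
                conc = float(overrides.get(comp.role, comp.concentration_mM))
                s = ideal_signal(
                    conc, comp.relaxation, tr_ms, te_ms, self.spec.scale_au_per_mM
                )
            else:
                s = comp.h1_amplitude * float(np.exp(-te_ms / comp.h1_t2star_ms))
            if s != 0.0:
                out[self.masks[comp.role]] = s
        return out

    def _render_coarse_ideal(
        self, nucleus: Nucleus, tr_ms: float, te_ms: float, overrides=None
    ) -> np.ndarray:
        fine = self._fine_ideal(nucleus, tr_ms, te_ms, overrides) * self.sensitivity_fine
        if self.spec.psf_mode == "block_average":
            return block_mean(fine, self.factors)
        sigma = self.spec.psf_fwhm_mm * _FWHM_TO_SIGMA / self.spec.fine_voxel_mm
        smoothed = gaussian_filter(fine, sigma=sigma, mode="nearest")
        return block_mean(smoothed, self.factors)

    def _add_noise(self, data: np.ndarray, sigma: float, rng) -> np.ndarray:
        if sigma <= 0 or rng is None:
            return data
        if self.spec.noise_model == "gaussian":
            return data + rng.normal(0.0, sigma, data.shape)
        re = data + rng.normal(0.0, sigma, data.shape)
        im = rng.normal(0.0, sigma, data.shape)
        return np.hypot(re, im)

    def render(
        self,
        nucleus: Nucleus = Nucleus.NA23,
        tr_ms: float = 15.0,
        te_ms: float = 0.1,
        rng: np.random.Generator | None = None,
        shift_voxels=None,
        averages: int = 1,
        concentration_overrides=None,
    ) -> Volume3D:
        """One acquisition: ideal image x sensitivity, downsampled, shifted, noisy.

        Sodium volumes land on the coarse grid, proton volumes on the fine
        grid.  ``shift_voxels`` is an integer shift on the output grid applied
        before noise (emulating inter-acquisition motion); noise standard
        deviation is divided by ``sqrt(averages)``.  ``concentration_overrides``
        maps a compartment role to a replacement concentration in mM, letting
        cohort sweeps reuse one rasterization.
        """
        nucleus = Nucleus(nucleus)
        if nucleus is Nucleus.NA23:
            data = self._render_coarse_ideal(nucleus, tr_ms, te_ms, concentration_overrides)
            voxel = float(self.spec.coarse_voxel_mm)
            sigma = self.noise_sigma
        else:
            data = self._fine_ideal(nucleus, tr_ms, te_ms, concentration_overrides) * self.sensitivity_fine
            voxel = float(self.spec.fine_voxel_mm)
            sigma = self.spec.h1_noise_sigma
        if shift_voxels is not None:
            shift = tuple(int(s) for s in shift_voxels)
            data = np.roll(data, shift, axis=(0, 1, 2))
        data = self._add_noise(data, sigma / np.sqrt(max(averages, 1)), rng)
        return Volume3D(data, np.full(3, voxel), np.zeros(3), nucleus, tr_ms=tr_ms, te_ms=te_ms)

    def render_sensitivity_scan(
        self, rng: np.random.Generator | None = None, averages: int = 20
    ) -> Volume3D:
        """Coarse-grid scan of a homogeneous 154 mM phantom filling the FOV."""
        cfg = self.config
        s = ideal_signal(
            154.0, WATER_RELAXATION, cfg.sensitivity_tr_ms, cfg.sensitivity_te_ms,
            self.spec.scale_au_per_mM,
        )
        data = s * self.sensitivity_coarse
        data = self._add_noise(data, self.noise_sigma / np.sqrt(max(averages, 1)), rng)
        return Volume3D(
            data,
            np.full(3, float(self.spec.coarse_voxel_mm)),
            np.zeros(3),
            Nucleus.NA23,
            tr_ms=cfg.sensitivity_tr_ms,
            te_ms=cfg.sensitivity_te_ms,
        )

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            concentrations_mM={c.role.name: c.concentration_mM for c in self.spec.compartments},
            relaxations={c.role.name: c.relaxation for c in self.spec.compartments},
            fractions=self.fractions,
            noise_sigma=self.noise_sigma,
            true_snr=self.true_snr,
            scale_au_per_mM=self.spec.scale_au_per_mM,
            tendon_roles=tuple(r.name for r in self.tendon_roles),
        )


def render_acquisition(
    spec: PhantomSpec,
    nucleus: Nucleus,
    tr_ms: float,
    te_ms: float,
    seed: int | None = None,
    config: StudyConfig | None = None,
    shift_voxels=None,
) -> Volume3D:
    """Convenience wrapper: rasterize ``spec`` and render one acquisition."""
    phantom = Phantom(spec, config)
    rng = np.random.default_rng(seed) if seed is not None else None
    return phantom.render(nucleus, tr_ms, te_ms, rng=rng, shift_voxels=shift_voxels)


@dataclass
class StudyBundle:
    """All volumes, masks and truth of one synthetic subject."""

    spec: PhantomSpec
    config: StudyConfig
    t1_volumes: list          # protocol 1: one 23Na volume per TR
    t2_volumes: list          # protocol 2: one 23Na volume per TE
    quant_volume: Volume3D    # protocol 3
    h1_volumes: list          # proton multi-echo set
    sensitivity_volume: Volume3D
    fine_mask: LabelMap
    coarse_mask: LabelMap
    ground_truth: GroundTruth
    manifest: dict

    @property
    def n_volumes(self) -> int:
        return len(self.t1_volumes) + len(self.t2_volumes) + 1 + len(self.h1_volumes) + 1


def generate_study(
    spec: PhantomSpec, config: StudyConfig | None = None, seed: int | None = None
) -> StudyBundle:
    """Generate one complete synthetic study.

    Every acquisition consumes its own child of ``seed`` (spawned in a fixed
    order from ``numpy.random.SeedSequence``), so the bundle is deterministic
    in ``(spec, config, seed)`` and changing the seed changes only the noise,
    never the geometry.
    """
    config = config or StudyConfig()
    phantom = Phantom(spec, config)
    n_rngs = len(config.tr_list_ms) + len(config.te_list_ms) + 1 + len(config.h1_te_list_ms) + 1
    if seed is None:
        rngs = [None] * n_rngs
    else:
        rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_rngs)]
    it = iter(rngs)
    shifts = dict(spec.shift_voxels)

    t1_volumes = [
        phantom.render(Nucleus.NA23, tr, config.t1_te_ms, rng=next(it),
                       shift_voxels=shifts.get(f"t1:{i}"))
        for i, tr in enumerate(config.tr_list_ms)
    ]
    t2_volumes = [
        phantom.render(Nucleus.NA23, config.t2star_tr_ms, te, rng=next(it),
                       shift_voxels=shifts.get(f"t2:{i}"))
        for i, te in enumerate(config.te_list_ms)
    ]
    quant_volume = phantom.render(
        Nucleus.NA23, config.quant_tr_ms, config.quant_te_ms, rng=next(it),
        shift_voxels=shifts.get("quant"),
    )
    h1_volumes = [
        phantom.render(Nucleus.H1, config.h1_tr_ms, te, rng=next(it),
                       shift_voxels=shifts.get(f"h1:{i}"))
        for i, te in enumerate(config.h1_te_list_ms)
    ]
    sensitivity_volume = phantom.render_sensitivity_scan(rng=next(it))

    manifest = {
        "seed": seed,
        "volumes": {
            "t1": [f"t1_tr{tr:g}.nii.gz" for tr in config.tr_list_ms],
            "t2": [f"t2_te{te:g}.nii.gz" for te in config.te_list_ms],
            "quant": "quant.nii.gz",
            "h1": [f"h1_te{te:g}.nii.gz" for te in config.h1_te_list_ms],
            "sensitivity": "sensitivity_scan.nii.gz",
        },
        "masks": {"fine": "mask_fine.nii.gz", "coarse": "mask_coarse.nii.gz"},
        "ground_truth": "ground_truth.json",
        "n_volumes": n_rngs,
    }
    return StudyBundle(
        spec=spec,
        config=config,
        t1_volumes=t1_volumes,
        t2_volumes=t2_volumes,
        quant_volume=quant_volume,
        h1_volumes=h1_volumes,
        sensitivity_volume=sensitivity_volume,
        fine_mask=phantom.fine_mask,
        coarse_mask=phantom.coarse_mask,
        ground_truth=phantom.ground_truth(),
        manifest=manifest,
    )


def cohort_spec(
    base: PhantomSpec,
    rng: np.random.Generator,
    concentration_cv: float = 0.10,
) -> PhantomSpec:
    """Per-subject variant of a spec with lognormal concentration jitter.

    Emulates between-subject biological spread of tendon sodium content while
    keeping geometry and noise level fixed.
    """
    comps = []
    for comp in base.compartments:
        if comp.role in (Role.TENDON,) + tuple(SEGMENT_ROLES) and comp.concentration_mM > 0:
            factor = float(np.exp(rng.normal(0.0, concentration_cv)))
            comps.append(dataclasses.replace(comp, concentration_mM=comp.concentration_mM * factor))
        else:
            comps.append(comp)
    return dataclasses.replace(base, compartments=tuple(comps))
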