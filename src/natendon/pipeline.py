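"""End-to-end orchestration: simulate -> preprocess -> fit -> quantify -> stats.

A *study* is one subject's bundle of acquisitions; a *run* analyses one or
more synthetic subjects and writes report tables.  All randomness flows from
one run seed through ``numpy.random.SeedSequence`` children (one per subject,
one per acquisition), so a run is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import io as nio
from .datamodel import (
    LabelMap,
    PHANTOM_RELAXATION,
    RelaxationParams,
    Role,
    SEGMENT_ROLES,
    StudyConfig,
    TENDON_RELAXATION,
    VIAL_ROLES,
)
from .phantom import GroundTruth, Phantom, PhantomSpec, StudyBundle, cohort_spec, generate_study
from .preprocess import apply_sensitivity_correction, estimate_sensitivity_map, register_translation
from .quantify import compute_atsc, fit_calibration, partial_volume_fraction, roi_stats
from .relaxometry import fit_t1_saturation_recovery, fit_t2star_biexponential, fit_t2star_mono_map, roi_mean_series
from .roi import segment_tendon_mask, transfer_mask
from .stats import build_report

__all__ = [
    "AnalysisOptions",
    "SubjectResult",
    "analyze_study",
    "run_pipeline",
    "save_study",
    "load_study",
]

log = logging.getLogger("natendon")


@dataclass
class AnalysisOptions:
    """Tunable knobs of the analysis chain (defaults are the study settings)."""

    smoothing_fwhm_mm: float = 6.0
    validity_fraction: float = 0.05
    max_shift_voxels: int = 2
    inclusion_threshold: float = 0.5
    vial_inclusion_threshold: float = 1.0
    min_noise_voxels: int = 100
    use_fitted_relaxation: bool = False
    tissue_relaxation: Mapping[str, RelaxationParams] = field(
        default_factory=lambda: dict(TENDON_RELAXATION)
    )
    phantom_relaxation: RelaxationParams = PHANTOM_RELAXATION
    fit_h1_map: bool = True
    register_series: bool = True


@dataclass
class SubjectResult:
    """All per-subject outputs of one analysis."""

    quant: object
    fits: dict                 # ROI name -> (t1 FitResult, t2* FitResult)
    coarse_labels: LabelMap
    calibration: object
    registration_shifts: dict
    h1_map: object = None
    qc: dict = field(default_factory=dict)


def _compose_coarse_labels(seg_fine: LabelMap, coarse_voxel_mm, options: AnalysisOptions) -> LabelMap:
    """Transfer the fine mask to the sodium grid.

    Tendon segments / noise use the standard inclusion threshold; reference
    vials keep only fully covered voxels so calibration is not diluted by rim
    partial volume.
    """
    base = transfer_mask(seg_fine, coarse_voxel_mm, options.inclusion_threshold)
    vial_codes = [int(r) for r in VIAL_ROLES if int(r) in seg_fine.legend]
    if vial_codes:
        strict = transfer_mask(seg_fine, coarse_voxel_mm, options.vial_inclusion_threshold)
        labels = base.labels.copy()
        for code in vial_codes:
            labels[labels == code] = 0
            labels[strict.labels == code] = code
        legend = dict(base.legend)
        for code in vial_codes:
            legend[code] = seg_fine.legend[code]
        return LabelMap(labels, base.voxel_size_mm, base.origin_mm, legend)
    return base


def analyze_study(bundle: StudyBundle, options: AnalysisOptions | None = None) -> SubjectResult:
    """Run the full single-subject analysis on a study bundle."""
    opt = options or AnalysisOptions()
    cfg = bundle.config

    # --- coil sensitivity -------------------------------------------------
    smap = estimate_sensitivity_map(
        bundle.sensitivity_volume, opt.smoothing_fwhm_mm, opt.validity_fraction
    )
    corrected, valid = apply_sensitivity_correction(bundle.quant_volume, smap)

    # --- masks ------------------------------------------------------------
    fine = bundle.fine_mask
    if int(Role.TENDON) in fine.legend:
        seg_fine = segment_tendon_mask(fine, Role.TENDON, cfg.segment_length_mm)
    else:
        seg_fine = fine
    coarse_voxel = bundle.quant_volume.voxel_size_mm
    coarse_labels = _compose_coarse_labels(seg_fine, coarse_voxel, opt)

    # --- motion correction -------------------------------------------------
    shifts = {}
    t1_volumes, t2_volumes = list(bundle.t1_volumes), list(bundle.t2_volumes)
    if opt.register_series:
        for name, series in (("t1", t1_volumes), ("t2", t2_volumes)):
            for i in range(1, len(series)):
                reg = register_translation(series[i], series[0], opt.max_shift_voxels)
                series[i] = reg.resampled
                shifts[f"{name}:{i}"] = reg.shift

    # --- ROI-mean relaxometry ----------------------------------------------
    seg_codes = {r.name: int(r) for r in SEGMENT_ROLES}
    roi_codes = dict(seg_codes)
    roi_codes["Total"] = [int(r) for r in SEGMENT_ROLES]
    for role in VIAL_ROLES:
        if int(role) in coarse_labels.legend:
            roi_codes[role.name] = int(role)
    fits = {}
    if t1_volumes and t2_volumes:
        for name, code in roi_codes.items():
            tr, y1 = roi_mean_series(t1_volumes, coarse_labels, code, time_attr="tr_ms")
            te, y2 = roi_mean_series(t2_volumes, coarse_labels, code, time_attr="te_ms")
            fits[name] = (fit_t1_saturation_recovery(tr, y1), fit_t2star_biexponential(te, y2))

    # --- tissue relaxation for the correction ------------------------------
    tissue_relax = dict(opt.tissue_relaxation)
    if opt.use_fitted_relaxation:
        if not fits:
            raise ValueError(
                "relaxometry stage needs the protocol-1 (TR series) and protocol-2 "
                "(TE series) volumes; supply tissue_relaxation to quantify without them"
            )
        for name in ("INS", "MID", "MTJ", "Total"):
            t1_fit, t2_fit = fits[name]
            if t1_fit.t1_ms and t2_fit.t2s_ms and not t2_fit.degenerate:
                tissue_relax[name] = RelaxationParams(
                    t1_fit.t1_ms, t2_fit.t2s_ms, t2_fit.t2l_ms, t2_fit.ps
                )

    # --- calibration --------------------------------------------------------
    vial_means = []
    for role in VIAL_ROLES:
        mask = coarse_labels.mask(int(role)) & valid
        if not mask.any():
            raise ValueError(f"no coarse voxels for {role.name}; cannot calibrate")
        vial_means.append(float(corrected.data[mask].mean()))
    calibration = fit_calibration(vial_means, cfg.vial_concentrations_mM)

    # --- partial volume ------------------------------------------------------
    pvs = {}
    for name in ("INS", "MID", "MTJ"):
        roi_mask = coarse_labels.mask(seg_codes[name])
        pvs[name] = partial_volume_fraction(
            seg_fine, seg_codes[name], coarse_voxel, opt.inclusion_threshold, roi_mask=roi_mask
        )
    total_mask = np.isin(coarse_labels.labels, list(seg_codes.values()))
    pvs["Total"] = partial_volume_fraction(
        seg_fine, list(seg_codes.values()), coarse_voxel, opt.inclusion_threshold,
        roi_mask=total_mask,
    )

    # --- aTSC ---------------------------------------------------------------
    quant = compute_atsc(
        corrected, coarse_labels, calibration, tissue_relax, opt.phantom_relaxation,
        pvs, regions=("INS", "MID", "MTJ"), valid=valid,
    )

    # --- SNR (undefined on noise-free data: zero noise SD) -------------------
    from .quantify import compute_snr  # local import keeps module top uncluttered

    noise_sd = float(bundle.quant_volume.data[coarse_labels.mask(int(Role.NOISE))].std(ddof=1))
    if noise_sd > 0:
        for name in ("INS", "MID", "MTJ"):
            quant.snr[name] = compute_snr(
                bundle.quant_volume, coarse_labels, seg_codes[name], coarse_labels,
                int(Role.NOISE), opt.min_noise_voxels,
            )
        quant.snr["Total"] = roi_stats(bundle.quant_volume.data[total_mask] / noise_sd)
    else:
        quant.qc["snr_skipped"] = "noise ROI has zero standard deviation (noise-free data)"

    # --- proton T2* map ------------------------------------------------------
    h1_map = None
    qc = dict(quant.qc)
    if opt.fit_h1_map and bundle.h1_volumes:
        h1_map, h1_qc = fit_t2star_mono_map(
            bundle.h1_volumes, seg_fine, codes=list(seg_codes.values())
        )
        qc["h1_map"] = {k: v for k, v in h1_qc.items() if k != "fitted"}
        fitted = h1_qc["fitted"]
        for name in ("INS", "MID", "MTJ"):
            sel = seg_fine.mask(seg_codes[name]) & fitted
            if sel.any():
                quant.h1_t2star[name] = roi_stats(h1_map.data[sel])
        sel = np.isin(seg_fine.labels, list(seg_codes.values())) & fitted
        if sel.any():
            quant.h1_t2star["Total"] = roi_stats(h1_map.data[sel])

    qc["registration_shifts"] = {k: list(v) for k, v in shifts.items()}
    qc["sensitivity_invalid_voxels"] = int((~valid).sum())
    return SubjectResult(
        quant=quant,
        fits=fits,
        coarse_labels=coarse_labels,
        calibration=calibration,
        registration_shifts=shifts,
        h1_map=h1_map,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# study persistence
# ---------------------------------------------------------------------------

def save_study(bundle: StudyBundle, directory) -> Path:
    """Write a study bundle (volumes, masks, ground truth, manifest) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    man = bundle.manifest
    for vol, name in zip(bundle.t1_volumes, man["volumes"]["t1"]):
        nio.save_volume(vol, directory / name)
    for vol, name in zip(bundle.t2_volumes, man["volumes"]["t2"]):
        nio.save_volume(vol, directory / name)
    nio.save_volume(bundle.quant_volume, directory / man["volumes"]["quant"])
    for vol, name in zip(bundle.h1_volumes, man["volumes"]["h1"]):
        nio.save_volume(vol, directory / name)
    nio.save_volume(bundle.sensitivity_volume, directory / man["volumes"]["sensitivity"])
    nio.save_label_map(bundle.fine_mask, directory / man["masks"]["fine"])
    nio.save_label_map(bundle.coarse_mask, directory / man["masks"]["coarse"])
    (directory / man["ground_truth"]).write_text(
        json.dumps(bundle.ground_truth.to_jsonable(), indent=1)
    )
    manifest = dict(man)
    manifest["config"] = dataclasses.asdict(bundle.config)
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return directory


def load_study(directory) -> StudyBundle:
    """Load a study bundle written by :func:`save_study`.

    The phantom spec itself is not reconstructed (analysis never needs it);
    the ground-truth record keeps its serialized summary form.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {directory}")
    man = yaml.safe_load(manifest_path.read_text())
    cfg = StudyConfig(**{
        k: v for k, v in man.get("config", {}).items()
        if k in StudyConfig.__dataclass_fields__
    })

    def _load(name):
        p = directory / name
        if not p.exists():
            raise FileNotFoundError(f"study at {directory} is missing {name}")
        return nio.load_volume(p)

    gt_raw = json.loads((directory / man["ground_truth"]).read_text())
    ground_truth = GroundTruth(
        concentrations_mM=gt_raw.get("concentrations_mM", {}),
        relaxations={
            k: RelaxationParams(**v) for k, v in gt_raw.get("relaxations", {}).items()
        },
        fractions={},
        noise_sigma=gt_raw.get("noise_sigma", 0.0),
        true_snr=gt_raw.get("true_snr"),
        scale_au_per_mM=gt_raw.get("scale_au_per_mM", 1.0),
        tendon_roles=tuple(gt_raw.get("tendon_roles", ())),
    )
    return StudyBundle(
        spec=None,
        config=cfg,
        t1_volumes=[_load(n) for n in man["volumes"]["t1"]],
        t2_volumes=[_load(n) for n in man["volumes"]["t2"]],
        quant_volume=_load(man["volumes"]["quant"]),
        h1_volumes=[_load(n) for n in man["volumes"]["h1"]],
        sensitivity_volume=_load(man["volumes"]["sensitivity"]),
        fine_mask=nio.load_label_map(directory / man["masks"]["fine"]),
        coarse_mask=nio.load_label_map(directory / man["masks"]["coarse"]),
        ground_truth=ground_truth,
        manifest=man,
    )


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_pipeline(
    out_dir,
    seed: int,
    spec: PhantomSpec | None = None,
    config: StudyConfig | None = None,
    n_subjects: int = 1,
    options: AnalysisOptions | None = None,
    concentration_cv: float = 0.10,
    write_volumes: bool = False,
) -> dict:
    """Simulate and analyse a synthetic cohort; write tables, QC and a log.

    Subject ``i`` consumes the ``i``-th child of ``SeedSequence(seed)`` (one
    grandchild for concentration jitter, one for the acquisitions).  Returns
    a dict with the subject results, report tables and output paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        spec = spec or PhantomSpec()
        config = config or StudyConfig()
        options = options or AnalysisOptions()
        children = np.random.SeedSequence(seed).spawn(n_subjects)
        subject_results, quants = [], []
        for i, child in enumerate(children):
            t0 = time.perf_counter()
            jitter_seq, acq_seq = child.spawn(2)
            subj_spec = spec
            if n_subjects > 1 and concentration_cv > 0:
                subj_spec = cohort_spec(
                    spec, np.random.default_rng(jitter_seq), concentration_cv
                )
            acq_seed = int(acq_seq.generate_state(1)[0] % (2**31))
            bundle = generate_study(subj_spec, config, acq_seed)
            if write_volumes:
                save_study(bundle, out_dir / f"subject_{i:02d}")
            result = analyze_study(bundle, options)
            subject_results.append(result)
            quants.append(result.quant)
            log.info("subject %d analysed in %.1f s", i, time.perf_counter() - t0)

        relax_fits = {
            name: [r.fits[name] for r in subject_results]
            for name in subject_results[0].fits
        }
        tables = build_report(quants, relax_fits)
        paths = {}
        for name, df in tables.items():
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        qc = {
            "seed": seed,
            "n_subjects": n_subjects,
            "subjects": [r.qc for r in subject_results],
        }
        qc_path = out_dir / "qc.json"
        qc_path.write_text(json.dumps(qc, indent=1, default=str))
        paths["qc"] = qc_path
        log.info("run complete: %s", ", ".join(str(p) for p in paths.values()))
        return {"subjects": subject_results, "tables": tables, "paths": paths}
    finally:
        log.removeHandler(handler)
        handler.close()
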