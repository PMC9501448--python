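# natendon

Quantitative sodium (²³Na) MRI analysis of the human Achilles tendon.

Sodium MRI probes the glycosaminoglycan (GAG) content of connective tissue:
negatively charged GAG side chains attract Na⁺ ions, so the sodium signal
tracks proteoglycan density, which changes early in tendinopathy — before
anything is visible on morphological images.  Raw ²³Na SNR depends heavily on
coil, sequence and resolution, so the comparable quantity is the **apparent
tissue sodium concentration (aTSC)**, obtained by calibrating the sodium
image against reference vials of known concentration and correcting for
relaxation weighting and partial-volume dilution.

This package implements that full analysis chain for surface-coil tendon
studies, together with a synthetic digital-phantom generator that emulates
the acquisitions with known ground truth, so every stage can be verified
end to end.  It is aimed at researchers developing or validating X-nucleus
quantification pipelines.

## The models

**Relaxometry** (ROI-mean series).  Longitudinal relaxation is estimated from
a saturation-recovery series over repetition times TR,

    S(TR) = S0 · (1 − e^(−TR/T1)) + offset,

and transverse relaxation from a multi-echo series over echo times TE with
the biexponential decay of spin-3/2 nuclei,

    S(TE) = S0 · (ps·e^(−TE/T2s*) + (1−ps)·e^(−TE/T2l*)) + offset,

where `ps` (0 < ps < 1) is the amplitude fraction of the short component —
theoretically 3/5 for a single sodium pool, since the satellite transitions
of the 3:4:3 multiplet relax fast.  Proton T2* is mapped voxel-wise with a
monoexponential plus offset.

**Quantification.**  With a straight-line calibration `S ≈ slope·C +
intercept` over the vial ROI means,

    aTSC = (S − intercept)/slope · f_phantom/f_tissue · 1/⟨fraction⟩,

where `f = (1 − e^(−TR/T1))(ps·e^(−TE/T2s*) + (1−ps)·e^(−TE/T2l*))` is the
relaxation weighting factor of tissue or vial at the acquisition TR/TE, and
⟨fraction⟩ is the mean coverage of the coarse (2 mm) sodium voxels by the
fine (1 mm) tendon mask — the partial-volume correction.  SNR is the ROI
signal divided by the standard deviation of a dedicated noise ROI.  Regions
(INS = calcaneal insertion, MID = mid-portion, MTJ = myotendinous junction;
consecutive 3-cm segments from the distal end) are compared with a Friedman
test followed by Bonferroni-corrected paired Wilcoxon signed-rank tests.

## Worked example

```python
from natendon import (AnalysisOptions, PhantomSpec, StudyConfig,
                      analyze_study, generate_study)
from natendon.phantom import regional_tendon_compartments

spec = PhantomSpec(
    compartments=regional_tendon_compartments(),  # INS/MID/MTJ at 112.9/77.3/55.3 mM
    target_snr=11.7,
)
bundle = generate_study(spec, StudyConfig(), seed=42)
result = analyze_study(bundle, AnalysisOptions())
for region in ("INS", "MID", "MTJ", "Total"):
    a, s = result.quant.atsc[region], result.quant.snr[region]
    h = result.quant.h1_t2star[region]
    print(f"{region:6s} aTSC {a.mean:6.1f} mM (SD {a.rel_sd_pct:4.1f} %)   "
          f"SNR {s.mean:5.2f}   1H T2* {h.mean:4.2f} ms")
t1f, t2f = result.fits["Total"]
print(f"whole-tendon fits: T1 = {t1f.t1_ms:.1f} ms, T2s* = {t2f.t2s_ms:.2f} ms, "
      f"T2l* = {t2f.t2l_ms:.1f} ms, ps = {100*t2f.ps:.1f} %")
```

prints

```
INS    aTSC  113.2 mM (SD 29.0 %)   SNR 17.52   1H T2* 2.10 ms
MID    aTSC   77.1 mM (SD 30.6 %)   SNR 11.59   1H T2* 2.10 ms
MTJ    aTSC   55.1 mM (SD 32.3 %)   SNR  7.18   1H T2* 2.10 ms
Total  aTSC   82.2 mM (SD 48.1 %)   SNR 11.82   1H T2* 2.10 ms
whole-tendon fits: T1 = 18.4 ms, T2s* = 1.38 ms, T2l* = 14.1 ms, ps = 31.0 %
```

The per-region aTSC recovers the generating concentrations to within the
noise; the within-ROI SD (~30 %) reflects partial-volume heterogeneity at a
whole-tendon SNR of 11.7.  The fitted whole-tendon T1 sits below the
region-wise mean because the high-signal insertion region dominates the
pooled ROI.  A command-line interface mirrors the library
(`natendon simulate | fit-t1 | fit-t2star | map-h1-t2star | segment-roi |
quantify | stats | report | run-all`).

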