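# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Units are mm, ms, mM and
arbitrary signal units (a.u.) throughout; voxel indices are 0-based, world
position = origin + index · voxel size, and axis 2 (the slice axis) runs
along the tendon from the calcaneal insertion (distal) to proximal.

## Signal model and relaxometry

Sodium nuclei have spin 3/2; in an ordered environment the two satellite
transitions of the 3:4:3 multiplet relax fast, giving a biexponential
transverse decay with a theoretical short-component fraction ps = 3/5 for a
single pool. Tendon tissue is not a single pool and shows ps ≈ 0.32. The
package fits

* `S(TR) = S0 (1 − e^(−TR/T1)) + offset` on saturation-recovery series
  (bounds S0 ≥ 0, T1 ∈ [0.1, 500] ms), and
* `S(TE) = S0 (ps e^(−TE/T2s*) + (1−ps) e^(−TE/T2l*)) + offset`
  (0 < ps < 1, 0.05 ≤ T2s*, T2l* ≤ 200 ms)

by bounded trust-region least squares. The additive `offset` is a fitted
constant absorbing the noise floor of magnitude images; it is not a noise
distribution parameter. Sodium fits use ROI-mean series — single sodium
voxels are far too noisy for voxel-wise estimates — while proton T2* is
mapped voxel-wise with a monoexponential plus offset.

Optimizer details are deterministic by construction: T1 starts from a
two-point log estimate plus fixed fallbacks {5, 20, 100} ms; the
biexponential uses five fixed starts (ps ∈ {0.3, 0.6} × T2s* ∈ {1, 5} ms
with T2l* = 15 ms, plus an agarose-like start ps = 0.6, T2s* = 6, T2l* = 13),
taking the best SSE. Tolerances are set to machine precision
(ftol = xtol = gtol = 1e-15) so noise-free round trips recover parameters to
better than 1e-4 relative; multi-start stops early once a start reaches
numerical-precision SSE. Component labels are ordered (T2s* ≤ T2l*) after
fitting. A fit is flagged degenerate when the data are constant, when the two
components coincide within 1e-3 ms, or when a monoexponential fit matches the
biexponential SSE to within numerical precision (ps unidentifiable; the
common T2* is then reported in both slots). R² is computed on the full
fitted series including the offset, with SST about the sample mean; all
points are weighted uniformly because ROI-mean series have homogeneous noise.

## Quantification chain

With vial ROI means fitted as `S ≈ slope·C + intercept` (ordinary least
squares, intercept retained so the noise floor is absorbed rather than
biasing the slope), each voxel of the concentration-weighted sodium image is
converted and corrected as

    aTSC = (S − intercept)/slope · f_phantom/f_tissue(region) · 1/⟨fraction⟩(region)

* `f(T1, T2s*, T2l*, ps; TR, TE)` is the fraction of fully relaxed signal
  observed at the acquisition timing; the ratio `f_phantom/f_tissue` removes
  the relaxation-weighting difference between agarose vials and tendon. By
  default the tendon factors use the reported in-vivo regional means and the
  vial factor the pooled agarose mean (T1 38.5, T2s* 6.0, T2l* 13.0 ms,
  ps 60.2 %); `use_fitted_relaxation` switches to the subject's own fits.
* `⟨fraction⟩` is the mean number of fine-grid (1 mm) tendon voxels per
  coarse (2 mm) sodium voxel over the coarse ROI, divided by the block size —
  the partial-volume correction. The fraction is always averaged over the
  same coarse voxels as the signal: this makes the chain exactly invertible
  on noise-free block-averaged data (verified as a property test for
  arbitrary tube placements), and is why `partial_volume_fraction` accepts
  an explicit ROI mask when the region mask comes from competitive label
  transfer rather than simple thresholding.
* Negative per-voxel concentrations are possible under noise; they are kept
  in the ROI statistics (excluding them would bias means upward) and counted
  in the QC record.

ROI transfer from the proton to the sodium grid labels a coarse voxel with
the code of largest coverage fraction provided it reaches the inclusion
threshold (default 0.5, i.e. nearest-neighbour-like); ties resolve to the
more distal segment. Reference-vial ROIs instead keep only fully covered
voxels (threshold 1.0): rim voxels would dilute the vial means and tilt the
calibration line. SNR divides the voxel signal by the unbiased SD of a
dedicated signal-free noise ROI (n−1 convention everywhere; ≥100 noise
voxels required).

Coil sensitivity is estimated from a homogeneous 154 mM phantom scan:
Gaussian smoothing (FWHM 6 mm — enough to suppress residual noise without
flattening the falloff, playing the role of the 20 signal averages in the
acquisition), normalization to the maximum, and a validity threshold at 5 %
of the maximum. Correction is voxel-wise division on valid voxels; invalid
voxels are zeroed and excluded from all ROI statistics. Motion between the
long acquisitions is modelled and corrected as integer-voxel translation:
exhaustive normalized-cross-correlation search over a ±2-voxel window
(computed with one circular FFT cross-correlation, which is exact because
shifts are circular), ties broken by smallest shift magnitude then
lexicographic order; a best correlation below 0.1 triggers a warning.

## The synthetic generator

`Phantom`/`generate_study` emulate a complete surface-coil study in image
space: a tendon-like tube (radius 5 mm, length 95 mm so three 3-cm segments
fit with a remainder) and four agarose-like vials (radius 5 mm, height
35 mm, 50/75/100/125 mM) on a 1-mm grid in a 180-mm field of view, plus a
30-mm signal-free noise box. Acquisitions follow the study protocol: five
saturation-recovery TRs (8/9/10/15/25 ms at TE 0.1 ms), twelve echo times
(0.1–21.3 ms at TR 30 ms), one concentration-weighted scan (TR 15 / TE
0.1 ms), four proton echoes (0.1/3/6/9 ms) and a homogeneous sensitivity
scan with 20 averages — 23 volumes per subject. The tendon defaults to the
reported whole-tendon control values (82.2 mM, T1 20.4 ms, T2s* 1.4 ms,
T2l* 13.9 ms, ps 31.6 %); `regional_tendon_compartments` splits it into
INS/MID/MTJ at the reported regional concentrations (112.9/77.3/55.3 mM).

Rendering composes: closed-form ideal signal per compartment → coil
sensitivity → downsampling to the 2-mm sodium grid (block average by
default; a Gaussian-PSF mode approximates reconstruction smoothing) →
optional integer-voxel shift → additive Gaussian noise (Rician available
for magnitude-image realism; Gaussian is the default because the fitted
offset in the signal models absorbs a noise floor, not a Rician shape).
Noise level can be given directly or via a target whole-tendon SNR; in the
latter case sigma is set so that (mean noise-free coarse tendon signal)/sigma
equals the target exactly. Every acquisition draws from its own child of the
study seed (`numpy.random.SeedSequence` spawned in fixed order), so a bundle
is bit-reproducible and changing the seed changes only the noise. Synthetic
cohorts add lognormal between-subject concentration jitter with 10 % CV —
the reported between-subject spread (~17 % of the mean) includes measurement
noise, so the biological component is set smaller and the protocol noise
supplies the rest.

Two generator choices are deliberate idealizations that make analysis
properties exact rather than approximate: the sensitivity falloff
(exponential in depth from the coil plane at the minimum slice-axis face) is
sampled at coarse-voxel centres and held constant within each sodium voxel,
so that division by the true map inverts the attenuation exactly; and the
default tendon/segment boundaries are aligned with the coarse grid, so that
per-region inversion is exact as well. A skin compartment (~45 mM close to
the tendon) is available but off by default; with it on, the surrounding
tissue violates the zero-background assumption of the exact-inversion
property, which is precisely its purpose in robustness tests.

What the generator does **not** emulate: radial k-space acquisition,
gridding and reconstruction filtering (only an image-space PSF surrogate),
B0/B1 inhomogeneity, residual quadrupolar line shapes, subvoxel motion, or
anatomically realistic tendon cross-sections. Passing tests therefore
demonstrate the correctness of the analysis chain under its own stated
assumptions, not the accuracy of aTSC in vivo.

## Statistics

Regional comparisons treat INS/MID/MTJ of the same subjects as repeated
measures: a Friedman test (chi-square approximation with 2 df, ties
mid-ranked and tie-corrected — what standard statistics packages print; an
exact enumeration mode exists for n ≤ 8 and serves as the test oracle)
screens at alpha = 0.05, then the three pairs are compared with paired
Wilcoxon signed-rank tests, two-sided normal approximation **without**
continuity correction, p-values multiplied by 3 (Bonferroni) and capped at
1. For n = 10 subjects with consistent ordering this prints 0.015 per pair.
The no-continuity-correction choice is what reproduces that value; exact and
unpaired (rank-sum) variants are available behind flags. Pairs with all-zero
differences return p = 1. Report tables carry p-values rounded to three
decimals; machine outputs keep full precision.

## Problem sizes

The test suite and the acceptance script run the full-size study (180-mm
FOV) only where the check is about the study geometry itself (noise-free
aTSC inversion, SNR recovery); property sweeps and cohort statistics use a
geometrically identical 64 × 64 × 120 mm phantom, and the cohort
significance property uses 50 cohorts of 10 subjects rendered from one
cached rasterization. These sizes are the package's own choice of test
scale; all tolerances are independent of them.

## Known limitations

* ROI-mean relaxometry assumes the region is relaxation-homogeneous; pooled
  ROIs spanning regions with different T1 yield an effective,
  signal-weighted value (visible in the worked example).
* The partial-volume correction rescales the ROI mean; it cannot undo signal
  from adjacent sodium-bearing tissue (skin) leaking into tendon voxels.
* Registration is integer-voxel translation only; subvoxel or deformable
  motion is out of scope.
* The calibration inverts with the fitted intercept; if the true acquisition
  had a negligible floor this is harmless, but a strongly non-linear floor
  would bias low concentrations.
* Voxel-wise biexponential sodium fitting is intentionally not provided.
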