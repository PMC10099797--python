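# Methods

`hdomri` implements a quantitative deuterium (²H) brain-water imaging
analysis: forward modelling of spoiled multi-echo gradient-echo (MEGE)
signals from HDO, voxel-wise estimation of flip-angle, R1 and R2* maps,
tissue ROI statistics, heavy-water (D₂O) enrichment quantification, and
Monte-Carlo precision analysis of TR/TE sampling schemes.  This note
records the model, the estimation procedure, the synthetic-data conditions,
and the numerical and design choices a maintainer would want to know.

## Signal model

The steady-state spoiled gradient-echo signal at repetition time TR, echo
time TE and flip angle α is

    S(TR, TE) = A · sin α · (1 − E₁) / (1 − cos α · E₁) · exp(−R2* · TE),
    E₁ = exp(−R1 · TR)

with amplitude A absorbing spin density, coil sensitivity and gain.  Units
everywhere: times in ms, rates in 1/s (T = 1000/R), angles in degrees at
public interfaces (radians internally).  All model functions broadcast over
timing grids so scalar checks, protocol grids and voxel maps share one code
path.  The Ernst angle arccos(E₁) is provided as a closed-form check on the
signal maximisation.

## Two-stage map estimation

Mirroring how multi-TR MEGE data are analysed when no separate B1 map is
acquired:

1. **Flip-angle stage.**  Images are summed over echoes at each TR and each
   voxel's TR series is fitted to the saturation-recovery factor
   A′·sinα·(1−E₁)/(1−cosα·E₁) for (A′, α, R1), by bounded trust-region
   least squares with analytic Jacobians and three starts (the 3-parameter
   problem is ill-conditioned; α and R1 are strongly correlated over a
   TR range that ends well short of CSF T1).  Bounds: α ∈ [1°, 120°],
   R1 ∈ [0.2, 20] s⁻¹, A′ ≥ 0.
2. **Smoothing.**  B1 varies smoothly in space, so the α map is averaged
   over a 5×5×5 voxel neighbourhood.  The neighbourhood shrinks to
   in-volume voxels at the edges.  Voxels that converged on a parameter
   bound *are* included in the pool: at realistic noise roughly two thirds
   of single-voxel fits pin some parameter (usually R1) at a box bound, and
   because the three parameter errors are correlated, averaging only the
   unflagged subset selects a flip-angle population biased by ≈ +20°.
   Strict behaviour is available via `valid_flags=(0,)`.
3. **Relaxation stage.**  With the smoothed α fixed, each voxel's full
   (TR, TE) grid is fitted for (A, R1, R2*) by minimising the unweighted
   sum of squared residuals.  Initialisation: R2* from a log-linear fit of
   the TE decay at the longest TR, R1 carried from stage 1, A by projecting
   the data onto the unit-amplitude model.  Bounds: R1 ∈ [0.2, 20] s⁻¹,
   R2* ∈ [1, 500] s⁻¹.

Least squares on magnitude data assumes Gaussian errors.  Rician bias is
accepted, not corrected; at echo-summed SNR 16 it inflates GM T2* by
roughly 5–10% (quantified in the test suite by fitting the same phantom
under both noise models).

**Quality flags** partition every voxel: 0 fitted, 1 below the signal
threshold (skipped, NaN), 2 converged on a bound, 3 non-converged.  A
parameter pinned at a bound takes precedence over a non-convergence report,
because degenerate voxels (flat recovery curves) typically crawl along a
ridge to a bound and exhaust the iteration budget there.  ROI statistics
use flag-0 voxels only and report counts.

**Signal threshold.**  Foreground is `summed > floor + f·(p99 − floor)`
on the echo/TR-summed image, with `floor` the volume median (an estimate of
the magnitude-noise floor) and f = 0.05 by default.  On noiseless data the
median background is zero and this reduces to a plain fractional threshold;
without the floor term, Rician background at SNR 16 passes the threshold
wholesale.

Proton R2* maps use the same machinery with a mono-exponential
S₀·exp(−R2*·TE) fit of single-TR multi-echo data.

## Synthetic phantom (study conditions)

The phantom emulates the study's acquisition so every stage is testable
without data downloads:

* **Geometry** — nested ellipsoids: a GM shell around a WM core, two
  ellipsoidal lateral ventricles and a smaller cistern-like posterior blob
  labelled CSF.  Parametric, not atlas-based, to keep the package
  self-contained.  The cistern compartment is modelled as CSF-like; its
  in-vivo composition (vessels plus CSF) is not claimed.
* **Tissue parameters** — per-voxel T1/T2* drawn from each tissue's
  (mean, SD), truncated at ±3 SD: CSF 510 ± 100 / 90 ± 10 ms, GM 320 ± 50 /
  32 ± 1 ms, WM 290 ± 30 / 30 ± 1 ms (the in-vivo 7T deuterium group
  values).  Amplitudes default to 1.0 / 0.8 / 0.7 (CSF/GM/WM), a relative
  water-fraction proxy; configurable.
* **B1 field** — smooth quadratic droop, b1 = 1.05 − 0.10·r² in normalised
  coordinates (≈ ±5% over the head, representative of a birdcage coil at
  the ²H frequency), clipped to [0.5, 1.5]; constant-field option for
  smoothing-neutral tests.
* **Noise** — Rician by default (magnitude images), Gaussian as the
  fitting-theory option.  `sigma_for_snr` calibrates the per-acquisition σ
  so that the echo-summed image at the reference TR has the requested
  tissue-mean/background-SD ratio, accounting for the Rayleigh background
  SD factor √(2 − π/2) under Rician noise and for 1/√averages scaling per
  TR.  The study condition is SNR ≈ 16.
* **Dose uptake** — each ~50 ml dose of 70% D₂O contributes
  100·V·f/TBW atom % asymptotically, approached exponentially with a 12-min
  absorption half-life; natural abundance 0.015% is the baseline.  Brain
  dispersal is assumed as fast as blood absorption, consistent with the
  similar ROI time-courses observed in vivo.

What the phantom does **not** emulate: partial-volume mixing at tissue
interfaces, susceptibility-induced field gradients, k-space artefacts,
slice profiles, physiological drift.  Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to those effects.

## Known precision limit: CSF T1 at SNR 16

With TR ≤ 816 ms and CSF T1 ≈ 510 ms, the recovery curve barely bends over
the sampled range: the single-voxel flip-angle estimate has an SD of ~35°
and the smoothed α field is spatially correlated (windows share voxels), so
the ventricle median T1 inherits a per-realisation α offset.  Measured on
32³ phantoms across seeds, the CSF tissue-median T1 error at SNR 16 spans
roughly −1% to +12%; GM (many independent smoothing windows) recovers to
1–3% and all T2* medians to ~2% (the TE decay does not involve α).
Iterating the two-stage procedure does not move this fixed point; robust
(median) smoothing and tighter α bounds were evaluated and rejected (they
bias the opposite way).  This is the same limitation the in-vivo data show
as large per-visit CSF SDs, and it is precisely why a longer-TR sample is
valuable — see the precision simulation.  The corresponding acceptance
test asserts a 5% tolerance for all tissues and is expected to fail for
CSF T1 at these conditions; the failure is informative, not a defect of
the implementation.

## Precision simulation (TR = 1500 ms)

`simulate_t1_precision` repeats: synthesise one voxel's noiseless (TR, TE)
grid, add Rician noise, run the same two-stage estimator (saturation-
recovery fit for α, then the fixed-α dual fit).  Estimating α from the
data — rather than fixing it at truth — is essential: the α–T1 correlation
is what a long-TR sample breaks.  With α fixed at truth the extended/base
SD ratio is only ≈ 0.74 (Cramér–Rao) whereas with α estimated the bound
ratio is ≈ 0.42 and the Monte-Carlo ratio ≈ 0.5, i.e. adding a single
TR = 1500 ms measurement to the 68–816 ms scheme halves the CSF T1 SD.

Defaults: SNR 80 (chosen so the base scheme's CSF T1 robust SD is ≈ 100 ms,
the scale of the in-vivo between-visit spread), n_reps 500, noise referenced
to a GM-like voxel's echo-summed mean.  Spread is summarised as a robust SD
(1.4826·MAD) because at realistic noise a small fraction of replicates are
degenerate (flat recovery within noise, fit on a bound) and the plain SD is
dominated by them; both numbers are reported.  The ratio is insensitive to
SNR over 80–300 (0.52 ± 0.01 robust), which is why an exact match to the
unstated simulation settings of the original analysis is not needed.
Paired runs share one seed, so identical schemes give a ratio of exactly 1.

`scan_duration` is plain Cartesian-encoding arithmetic
(n_y·n_z·averages·TR summed over TRs) with a shutter-fraction knob;
vendor elliptical-shutter or partial-Fourier reductions are deliberately
not modelled, so console times ~5–25% shorter than the computed values are
expected.

## ROI statistics and tissue comparisons

Masks are binary NIfTI volumes applied after nearest-neighbour resampling
through composed voxel-to-world affines (pull resampling; images use
trilinear).  The manual pruning of the CSF mask down to the lateral
ventricles is replaced by a deterministic surrogate: keep the k largest
26-connected components (default k = 2).

Summary rounding reproduces the printed precision of the in-vivo table:
deuterium times ≥ 50 ms round to 10 ms, < 50 ms to 1 ms; proton times to
1 ms.  (A blanket nearest-10 rule fails the printed GM T2* mean of 32 ms.)
SDs are sample SDs (n − 1) and are reported unrounded; the printed table's
one-significant-figure SDs are too coarse to reproduce meaningfully.

Tissue comparisons use the classic pooled two-sample t-test (Welch
available).  On the per-visit values, CSF vs GM/WM for both T1 and T2*
give p ≤ 0.004, consistent with the reported p < 0.007 bound.  SNR is
tissue-mean over background-SD with no Rayleigh correction, matching the
conventional ROI estimate.

## Enrichment quantification

Total body water comes from the Watson sex-specific regressions (default)
or a configurable fraction of body mass.  D₂O volume over TBW volume is
used directly as the added deuterium atom fraction (both molecules carry
two hydrogen sites); isotope-exchange losses are ignored.  Spectroscopy
amplitudes are quantified by magnitude-spectrum summation in a
peak-centred window (no lineshape fitting) and converted to atom % by
scaling against the natural-abundance (0.015%) baseline signal; when the
baseline is too noisy, ROI time-courses are normalised instead to a
late-time reference value (the cistern at the final loading time point).

## Problem sizes

Default analysis grids in the tests and the acceptance script are
16×16×10 (noiseless recovery) and 28×28×14 (SNR-16 recovery) voxels, with
500-replicate precision simulations — sizes at which every stage's
statistical behaviour is resolved while the whole suite stays lightweight.
The fitted maps scale linearly in voxel count (bounded least squares per
voxel, ~5 ms each).

## Limitations

* Magnitude-data least squares (no Rician MLE); bias accepted and measured.
* No spatial regularisation of parameter maps; no complex-valued fitting.
* Mono-exponential T2* only; bi-exponential water pools are out of scope.
* Segmentation, registration, brain extraction and bias-field correction
  are consumed (as masks/affines), never computed.
* The phantom's geometry is parametric; anatomical realism is not claimed.
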