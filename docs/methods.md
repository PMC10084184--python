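# Methods

## Signal model

A MEX acquisition suppresses the free-water longitudinal magnetization with
selective pulses, waits a delay `t_LM`, and images. During the delay the
water signal recovers through two channels: magnetization exchanged from
the semisolid proton pool (time constant τ_exc) and ordinary spin–lattice
relaxation (T1). With fast exchange (τ_exc ≪ T1) and a 90° excitation the
fractional recovery is

    m(t) = F·(1 − e^(−t/τ_exc)) + (1 − F)·(1 − e^(−t/T1)),

with F the fraction of protons in semisolids. m is zero at t = 0, strictly
increasing, and approaches 1; for τ_exc ≪ t ≪ T1·F the curve plateaus near
F, which is why short delays image macromolecular content. The model
assumes a 90° flip angle; this is a documented precondition, not a fitted
parameter. All times are milliseconds throughout the package; unit
conversion belongs at the I/O boundary.

Because the scanner scale (equilibrium magnetization M0, coil gain) is
unknown, measured curves are normalized by the longest-delay volume and
the ratio m(t)/m(t_max) is fitted. The longest-delay MEX volume itself is
the normalizer — the model's denominator is the same two-pool expression
evaluated at t_max — rather than any separate reference scan.

Two delay schedules ship as presets:
rat {15, 50, 100, 200, 400, 800, 1600, 2500, 3000} ms and
mouse {15, 25, 50, 75, 100, 200, 600, 1200, 2500} ms.

## Fitting

`fit_curve` minimizes the sum of squared residuals of the normalized model
with scipy's trust-region reflective (`trf`) bounded least squares and an
analytic Jacobian. Choices that matter:

* **Parameters and bounds.** All three of (F, T1, τ_exc) are fitted.
  F ∈ [0, 1], T1 ∈ [100, 5000] ms, τ_exc ∈ [0.1, 200] ms; the τ_exc cap
  enforces the fast-exchange regime. Reports default to F and T1; τ_exc is
  retained on the result and in `tau_map`.
* **Initialization.** Fixed start (F, T1, τ) = (0.05, 1500 ms, 20 ms); on
  non-convergence up to 3 retries from deterministically perturbed starts
  (a fixed perturbation pattern, independent of the data). The first
  successful solve wins; otherwise the lowest-cost attempt is returned with
  `converged=False`.
* **Tolerances.** ftol = xtol = gtol = 1e−14. The problem is tiny
  (9 points, 3 parameters) and smooth; tight tolerances matter in the
  nearly flat valley at F → 0, where looser settings leave T1 off by
  ~0.1 ms.
* **Fit quality.** R² = 1 − SS_res/SS_tot is computed on the normalized
  values (the quantity actually fitted), not raw intensities. Confidence
  half-widths are the local linearization: σ² = SSR/(n−3), covariance
  σ²(JᵀJ)⁻¹ (pseudo-inverse for rank deficiency), multiplied by the
  t-quantile with n−3 degrees of freedom.
* **Degenerate inputs.** A constant curve has zero total variance and
  raises; a voxel whose t_max intensity is ≤ 1e−12 cannot be normalized
  and is skipped silently at map level (this is how high-liquid voxels
  such as vessels leave the ROI without manual editing); an all-false ROI
  is an error.

`fit_map` applies normalize + fit per ROI voxel and gates the output on
convergence and R² > 0.95 (configurable). `fit_roi` sums the raw signal
over the ROI per delay before normalizing and fitting once; summation
averages noise down, so the ROI fit reaches R² > 0.999 at SNR ≈ 50 with a
few hundred voxels.

Arrays are indexed (row, col, slice), analysis is voxel-space; NIfTI
affines are carried only through I/O round-trips.

## Map summaries

Histograms of valid-voxel F use bin width 0.01 on [0, 1] by default (the
width is a free choice; F values of interest live in [0, 0.3]). The high-F
fraction is 100 × #(valid ∧ F > 0.1)/#valid, with a strict lower inequality
and, optionally, an upper cap at 0.3 to reproduce the bounded
"upper range" variant. The denominator is valid voxels, not the full ROI,
so the summary does not depend on how many voxels the quality gate
removed.

## Histology gating

RGB sections are converted to YCbCr with the ITU-R BT.601 **studio-swing**
matrix (Y ∈ [16, 235], Cb/Cr ∈ [16, 240] for in-gamut inputs; scikit-image
implementation, rounded half-away-from-zero to uint8), the convention of
the common 8-bit thresholding tools under which the shipped PSR/MT gates
were defined. A full-swing JPEG-style conversion is available behind
`swing="full"` for gates defined under that convention; on real slides the
absolute fractions would shift if the wrong convention were chosen, while
the package's synthetic tests are convention-consistent by construction.
Gate intervals are inclusive on both ends (the `a:b` notation), and no
morphological cleanup is applied — the fraction is pure pixel counting.

## Group statistics

Welch's t-test (Welch–Satterthwaite df) for independent groups, paired t
(df = n−1, complete pairs) across timepoints, one-sided Welch tests for
ordinal inflammation contrasts, and Pearson correlation with the standard
OLS 95% prediction band
s·t_{n−2}·√(1 + 1/n + (x−x̄)²/Sxx). Per-test α = 0.05 with no multiplicity
correction, matching per-comparison reporting practice for such cohorts.
Degenerate conventions: two zero-variance samples with equal means give
t = 0, p = 1; zero-variance paired differences raise. Summaries are
mean ± SD across animals and mean ± CI95 for fitted parameters.

## Synthetic data

The generator defines the study conditions; it is configuration, not a
tuning knob.

* **Phantom.** Elliptical connected ROI (~55% of FOV), M0 = 100 inside and
  0 outside. Presets: `homogeneous`, `two_compartment`
  (F = 0.05 / 0.15 halves), and four group presets whose means/SDs are the
  YAML files under `mexmri/presets/`: rat control F 0.080 ± 0.003,
  rat fibrosis 0.10 ± 0.02, mouse control 0.042 ± 0.006 (T1 1436 ± 54 ms),
  mouse fibrosis 0.062 ± 0.006 (T1 1485 ± 160 ms). Fibrotic presets add a
  smooth low-order cosine field (amplitude 0.03, recentred so the ROI mean
  equals the group mean) to emulate spatially variable severity, plus three
  small vessels with F = 0.002.
* **Forward model.** Noiseless signal M0·[(1−s) + s·m(t)], where s is the
  suppression fraction. Residual suppression is modeled as the simplest
  consistent mechanism — an additive constant baseline (1−s)·M0 surviving
  the suppression block. At s = 0.98 the fitted F is biased high by at
  most 0.02 absolute (the baseline is absorbed mainly into the
  fast-exchange term); the in-vivo calibration ranges are recorded in the
  presets (rats 0.979–0.994, mice 0.982–0.996).
* **Noise.** Rician by default — magnitude images positively bias
  low-signal measurements — with σ = mean ROI M0 / SNR; Gaussian is a
  flag. Acquisition SNR is a free parameter (no measured value is
  available); tests use 10–100.
* **Cohorts.** Per-animal ROI-mean F and T1 are drawn from truncated
  normals at the preset means/SDs (truncation keeps F in [0.005, 0.5] and
  T1 in [200, 4500] ms); each animal gets a homogeneous phantom at its
  drawn truth so pipeline recovery is exactly checkable. Quantitative
  histology is linked linearly, histology% = a·F + b + ε clipped at 0,
  with (a, b) solved from the two group-mean points per species
  (rats: a = 346.1, b = −26.2 against PSR; mice: a = 175.4, b = −6.79
  against MT) — the negative intercept on the histology axis encodes that
  the regression does not pass through the origin (an F baseline from
  non-collagen macromolecules). ε defaults to SD 0.5% (rats) / 0.3%
  (mice), small relative to the group separations.
* **Stain images.** `make_stain_image` draws colors from an RGB-cube grid
  (step 8) verified in- or out-of-gate through the same conversion the
  segmenter uses, then places exactly round(fraction × pixels) in-gate
  pixels at shuffled positions — so the measured percentage equals the
  constructed one exactly, by counting.

What the generator does **not** emulate: anatomically realistic liver
geometry, respiratory motion, B0/B1 inhomogeneity, readout contrast (TE/TR
weighting beyond scalar M0), partial-volume mixing at organ boundaries, and
spatially correlated noise. Passing tests therefore demonstrate the
correctness of the estimation chain under the stated signal model, not
robustness to those in-vivo effects.

## Problem sizes

Tests and the acceptance script use 32×32 (560 ROI voxels) and 16×16
single-slice phantoms, 200-draw parameter-recovery sweeps, 200×200 stain
images and cohorts of 2–10 animals per group — sizes at which every result
above is deterministic and the full suite runs in well under a minute.

## Known limitations

* τ_exc is weakly identified when F is small (the fast-exchange term then
  contributes little); it is bounded rather than fixed, and not reported by
  default.
* R² on normalized values and the map-level exclusion rules are one of
  several defensible conventions; both are configurable.
* The suppression baseline is a single scalar per series; pulse-calibration
  drift within a scan is not modeled.
* The histology linkage is a two-point linear solve from group means, not
  a fitted animal-level relationship.
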