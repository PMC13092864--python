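# Methods

## Wave-trace pipeline

### Generative model

A wave-transit event is modeled per channel *c* as

    I_c(t) = [B_c + P_c · S((t − t_on − ℓ_c)/τ) · D_c(t)] · e^(−β t) + ε,
    ε ~ N(0, σ²)

- **Rise** *S(u)*: a logistic, clamped to exactly 0 for u ≤ 0 and rescaled
  so that S(3) = 0.95; the functional form of the rise is a modeling
  choice (real waves show a sigmoidal appearance without a canonical
  parametric form) picked for its smooth single inflection and closed-form
  anchors. τ (default 20 s) sets the rise time; the lag ℓ (default 30 s)
  applies only to the tropomyosin channel, encoding the observation that
  Tpm recruitment trails actin assembly.
- **Dispersal** *D_c(t)*: 1 until `t_offset`, then exponential decay at a
  channel-specific rate — defaults 0.02 s⁻¹ (actin) vs 0.008 s⁻¹ (Tpm),
  so the actin signal disperses faster than the Tpm signal.
- **Photobleaching**: one shared mono-exponential rate β (default
  0.001 s⁻¹) multiplies both the ROI and the whole-field signal, which is
  what makes whole-field ratio correction an exact inverse.
- **Noise**: additive Gaussian, default σ = 200 a.u. against a plateau of
  2000 a.u. (amplitude SNR 10). Read noise dominates at these intensity
  levels; a Poisson (shot-noise) variant is deliberately not modeled.
  Intensities are clipped at zero after adding noise (photon counts are
  non-negative); with default parameters the baseline sits 2.5 SD above
  zero, so clipping is a <1% tail event and is probed nowhere by the
  closed-form tests.
- **Cadence presets**: 15 s frames over 15 min (wave transit) and 1 s
  frames over 5 min (wave dynamics), matching the two acquisition modes
  such experiments use. Default onset t_on = 180 s and dispersal onset
  t_offset = 240 s give a sharply peaked actin trace (the rise is
  essentially complete when dispersal begins), which is what the real
  events look like and what makes peak ordering identifiable.

All generators take a mandatory integer seed and are bit-reproducible;
there is no global random state. Replicate ensembles
(`simulate_wave_ensemble`) stagger absolute onsets by whole frames while
shifting `t_offset` in lockstep, so replicates share one event shape in
wave-relative time.

### Analysis

1. **Photobleach correction** divides each ROI trace by its channel's
   whole-field trace normalized to frame 0. Noise-free, this inverts the
   generator's bleach term to < 1e-9 relative error (asserted in tests).
2. **Onset detection**: baseline mean/SD from the first `baseline_window`
   (10) frames; the first later frame above mean + k·SD (k = 3) marks the
   rise, and the frame before it is the inflection anchor. A zero-SD
   baseline falls back to a 5% relative-rise rule. Detection runs on the
   actin channel (the wave is defined by actin appearance) and anchors
   both channels of an event.
3. **Normalization** maps the anchor value to 0 and the plateau mean to 1.
   The plateau window is `plateau_frames` (5) frames centered on the
   post-inflection maximum of a 3-frame moving average — resistant to
   single-frame noise spikes. The map is affine, hence invariant under
   positive affine transforms of the raw trace (property-tested).
4. **Alignment** places replicates on a common grid anchored at the
   inflection (equal frame intervals required, tolerance 1e-6 s); mean,
   sample SD (n − 1) and replicate count are computed per grid point over
   covering traces. A single covering trace reports SD 0 with a warning.
5. **Significance windows** compare, at each post-inflection timepoint
   with ≥ `n_min` (3) replicates in both ensembles, the per-trace
   normalized values of the Tpm ensemble against the actin ensemble:
   Mann–Whitney two-sided p (exact enumeration when both sizes ≤ 8, else
   normal approximation with tie and continuity corrections) and Cliff's
   delta. A timepoint is significant when δ > 0.3 and p < 0.05 (signed
   delta by default — positive δ means Tpm above actin; an absolute-value
   flag exists). Analysis truncates at the last timepoint meeting the
   replicate floor, mirroring the truncation of under-replicated late
   timepoints in this kind of ensemble. Windows are maximal consecutive
   significant runs.

   The per-timepoint samples are the individual replicate traces' values,
   not the ensemble means: means carry no replicate structure to test.
   This is the one testable reading of comparing "average fluorescence
   plots" and is the documented interpretation.

## Titration analysis

Responses normalize per replicate to that replicate's 0 µM control
(control rows map to exactly 1; the operation is idempotent). Fitting
uses the decreasing Hill form in log₁₀-concentration space with the 0 µM
anchor excluded; top/bottom are fixed at 1/0 for normalized data (a
free-top variant is retained). Multi-start initialization places the IC50
at the observed concentration quartiles with Hill coefficients {1, 2, 4};
the best residual sum of squares wins, and noise-free data are recovered
to ≤ 1e-6 relative error from any start. The fit is scale-equivariant:
scaling all concentrations by *s* scales the fitted IC50 by *s*.

**Confidence interval.** The default 95% CI is a studentized residual
bootstrap: resample the variance-inflated fit residuals (scaled by
√(n/(n−p))), refit warm-started, form the bootstrap-t distribution of
log₁₀ IC50 using the linearized (Jacobian) standard error, and invert it.
This choice is deliberate: with 3 replicates per concentration,
percentile intervals from replicate- or stratified-observation resampling
systematically undercover (measured at 75–85% across calibration
simulations at both isoform scales), while the bootstrap-t interval is
second-order accurate and measures at 95–100% coverage under the same
conditions. Both percentile schemes remain available
(`bootstrap="stratified" | "replicate"`). All resampling is seeded.

Binding calls are binary per field of view: bound ⇔ filament count ≥ 5
(boundary inclusive; the count rule is this package's choice — binary
charts of this kind publish no numeric cutoff). Motile fraction is the
share of filaments at or above a speed threshold (default 50 nm/s, also
a package choice), optionally normalized to a control fraction.

## Track speeds

Speed is total path length over elapsed time — the quantity
frame-to-frame manual tracking measures — with net-displacement speed as
a secondary statistic (path ≥ net by the triangle inequality, and the
speed is rigid-motion invariant; both property-tested). Summaries
restrict to motile tracks; an all-immotile input yields n = 0 with NaN
mean, never a silent zero.

Isotropic per-step jitter biases path-length speed upward: a step of
length μ with N(0, σ²) jitter per coordinate has expected length equal to
the Rice-distribution mean ≈ μ + σ²/2μ (≈ 0.26 nm/s at 780 nm/s,
σ = 20 nm, 1 s frames). Recovery tests therefore compare against the
exact Rice expectation rather than the nominal speed; the bias is two
orders of magnitude below the measurement SD a gliding assay reports.

## Image quantification

- **Otsu threshold**: 256 uniform bins over the observed min–max
  (Fiji-compatible), between-class variance maximized, ties broken to the
  lowest qualifying threshold, foreground = values strictly above. The
  implementation is checked against an exhaustive brute-force split
  search and against an independent library implementation.
- **Mask enrichment**: Otsu mask from the organelle channel within an
  ROI, applied to the measurement channel. Reported: in-mask mean,
  integrated in-mask signal normalized by ROI pixel area (per-mask-area
  exposed as a named option), out-of-mask mean and the in/out enrichment
  ratio. No morphological post-processing by default. An empty mask
  (reachable only with an explicit threshold override) flags NaN
  statistics rather than zeros.
- **Line profiles**: bilinear sampling at 1 px steps along paired
  segments, one over the filament axis and one just off it;
  corrected signal = mean(on) − mean(off), offset-invariant and
  gain-equivariant.

The toy image generator draws disk-shaped organelles (uniform random
centers, fixed radius, bright in the organelle channel), multiplies the
measurement-channel background inside the true blob mask by the
enrichment factor, and draws 1-px filament line segments; Gaussian pixel
noise throughout. It does not model PSF blur, organelle shape variation,
uneven illumination, or 3D structure — so passing recovery tests
demonstrate the estimators' correctness on well-separated signals, not
robustness to optical artifacts.

## Problem sizes and numerical choices

- Recovery simulations use 20 seeds × 3 replicates (titrations), 10 seeds
  × 10 replicate events (waves), 100 tracks, and 50 images — sizes at
  which the Monte-Carlo standard errors are comfortably below the
  assertion tolerances.
- Exact Mann–Whitney enumeration is limited to both samples ≤ 8
  (C(16,8) = 12 870 assignments); beyond that the tie-corrected normal
  approximation with continuity correction takes over.
- Least-squares fits: point estimates use bounded trust-region fits from
  multiple starts (tolerances 1e-12); bootstrap refits warm-start from
  the point estimate with unbounded Levenberg–Marquardt for speed.
- Degenerate inputs are errors, not coercions: empty samples, constant
  images for Otsu, zero-length segments, non-positive whole-field
  frames, falling traces with no resolvable amplitude, duplicate
  timestamps, missing 0 µM controls.

## Known limitations

- The onset detector assumes a quiescent pre-wave baseline of at least
  `baseline_window` frames; events starting near the recording start are
  rejected rather than guessed.
- The significance test treats replicate traces as exchangeable and
  independent per timepoint; temporal autocorrelation within a trace is
  not modeled (matching the per-timepoint testing convention this
  analysis style uses).
- IC50 confidence intervals are calibrated under the generator's
  homoscedastic Gaussian noise; heavy-tailed measurement error would
  call for the replicate-resampling schemes instead.
- Wave analysis assumes both channels share one frame clock; no
  resampling across mismatched cadences is attempted.
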