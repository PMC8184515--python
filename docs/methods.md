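# Methods note

This note records the analysis model, the default parameters and the
numerical design choices behind `cascadefish`. Everything quantitative
stated here is either a definition or is computed by the test suite; no
empirical claim is made beyond what the tests verify.

## Preprocessing

**Onset discard.** The first `discard_frames` frames (default 100, i.e.
5 s at 20 fps) are dropped to remove the illumination-onset transient.

**ΔF/F.** For each pixel or neuron trace, the baseline at frame *t* is
the mean of the lower 50 % (the ⌊k/2⌋ smallest of the k available values,
minimum 1) of the raw trace over the strictly preceding window
[t−W, t−1], W = round(`dff_window_s` · fps) (default 10 s → 200 frames).
Frame 0 has no history and is set to 0; ramp-up frames use all preceding
frames. The estimator is *causal*: no future sample influences the
baseline, so an event cannot suppress its own normalization. Traces whose
baseline is ever non-positive or non-finite are flagged invalid, zeroed,
and logged as exclusions rather than propagating NaNs.

Why lower-half mean: it tracks slow multiplicative drift (a ±50 %
sinusoidal drift with 120 s period leaves a residual |ΔF/F| below 0.26,
verified in tests) while remaining insensitive to the sparse positive
transients that occupy the upper half of the window.

The rolling implementation maintains a sorted buffer incrementally
(numba-compiled, with a pure-numpy partition fallback) and is verified
frame-for-frame (< 1e-10) against an explicit double-loop reference.

## Cascade detection (mesoscale)

- **Binarization**: pixel active at frame *t* iff ΔF/F(t) > k · SD, with
  k = 5 and SD the per-pixel sample standard deviation (ddof = 1) of the
  full post-discard ΔF/F trace. Strict inequality; zero-variance pixels
  are logged and never active.
- **Clustering**: per-frame connected components (4-connectivity by
  default, 8 available) of ≥ `min_cluster_pixels` = 3 pixels; smaller
  groups are discarded as noise.
- **Linking**: a cluster at frame t+1 continues a cascade if it touches
  (overlap or edge/corner adjacency under the same connectivity) any
  pixel active in that cascade at frame t. A cluster touching several
  ongoing cascades merges them (union-find). Cascades end at the first
  frame with no continuing cluster; there are no temporal gaps.
- **Size** = cumulative number of (pixel, frame) activations;
  **duration** = frame span / fps; **peak extent** = largest single-frame
  cluster.

The optimized linker (per-frame label maps + union-find) is verified
against a verbatim nested-loop reference on random binary movies:
identical counts, footprints, sizes and durations.

**Duration bias.** With real indicator kinetics a single activation keeps
a pixel above the 5 SD threshold for the length of the decay tail, so
detected sizes and durations exceed the underlying activation counts.
This is a property of threshold crossing on slow indicators, not of the
linker; exact-recovery tests therefore use impulse-rendered transients
(below).

## Ensemble detection (microscale)

- **Event detection**: a frame *t* is an event onset iff, for some
  template, the Pearson correlation between the template and the trace
  segment starting at *t* exceeds 0.85 *and* the segment's peak ΔF/F
  exceeds 0.05. The template library is a grid of unit-peak
  double-exponential waveforms, rise τ ∈ {0.02, 0.05, 0.1} s × decay
  τ ∈ {0.2, 0.5, 1.0} s. Correlation is scale-free, so the amplitude gate
  is the only scale-dependent element.
- **Collapse rule**: one transient produces matches at a contiguous run
  of start frames (a segment starting a few frames early still correlates
  > 0.85 because the template head is near zero). Each contiguous run
  collapses to its best-correlated frame — a noise-free template copy
  therefore yields exactly one event at its true onset — and residual
  decay-tail re-matches within one template length of an accepted onset
  are suppressed. Consequence: two genuine events on the same neuron
  closer than one template length (up to ~4 s for the slowest template)
  can merge into one detected event.
- **Coactivity**: counts(t) = number of *distinct* neurons with ≥ 1 event
  in the trailing window [t−9, t] (10 frames = 0.5 s at 20 fps),
  truncated at the recording start.
- **Surrogate null**: each neuron's event frames are independently
  redrawn uniformly without replacement (`permute`; a circular-shift
  scheme that preserves inter-event structure is available by flag),
  2000 shuffles, coactivity recomputed, and all values pooled into one
  histogram. The critical value is the empirical 99.9th percentile
  (smallest value v with CDF(v) ≥ 0.999 · N); frames with counts
  *strictly greater* are significant. Runs of significant frames become
  ensemble events; members are the neurons with an event inside the
  run's window support; centroids and pairwise member distances use the
  pixel pitch (default 2.67 µm).

**Calibration is conservative.** Coactivity counts are small integers, so
the achievable significance level sits at a discrete quantile below the
nominal 10⁻³; on i.i.d. Bernoulli rasters (100 neurons, 6000 frames, rate
0.005) the flagged-frame fraction is ≈ 5.5 × 10⁻⁴. The acceptance test
checks the package against a Monte-Carlo interval computed by an
independent convolution-based implementation of the same discrete
procedure, not against the nominal level.

## Group statistics

Two-sample *t* (pooled variance by default, Welch optional), paired *t*
on post−pre differences, and the two-sided two-sample KS test. The KS
p-value uses scipy's exact method below a combined n of 25 and the
classical Kolmogorov (Smirnov limiting) asymptotic
p = Q(√(mn/(m+n)) · D) above it; the asymptotic formula is stated
explicitly because library implementations differ in their finite-n
corrections, and the test suite verifies the stated formula against an
independent series summation. Degenerate inputs (zero-variance groups or
differences) are flagged rather than returning NaN. Pre/post drug
comparisons first normalize each fish's metrics to its pre-treatment
mean (zero pre-means are flagged and excluded). Cohort comparisons
average epochs within subject first, so the experimental unit is the
fish.

## Synthetic data generator

Mesoscale movie model, per pixel:

F(t) = B · (1 + a·sin(2πt/P)) + B · A · s(t − t_act) + ε,  ε ~ N(0, (σ·B)²)

with defaults B = 1000 counts, drift amplitude a = 0.05, period
P = 120 s, noise σ = 0.02 (of baseline), fps = 20, 60×60 pixels, 6000
frames. Transient amplitudes A are therefore calibrated directly in ΔF/F
units. The transient shape s(·) is a unit-peak double exponential
(rise 0.05 s, decay 0.4 s) by default, or a single-frame impulse
(`transient_shape="impulse"`). Impulse rendering makes the injected
activation set equal to the super-threshold set, which is what makes
*exact* recovery of size and duration well-posed; with the realistic
kernel the decay tail adds activations (duration bias above) and the
kernel's zero-valued first sample shifts onsets. Injected cascades are
grown as guaranteed-contiguous random regions reseeded from the previous
frame's footprint.

Microscale rasters: per-neuron Bernoulli background events (default rate
0.002 per frame) plus forced ensemble events, convolved with the calcium
kernel at amplitude 0.2 ΔF/F, noise SD 0.01, neurons on a jittered grid.

What the generator emulates: slow multiplicative drift, indicator-shaped
transients, i.i.d. Gaussian pixel noise, contiguous propagation,
coactive groups. What it does not: motion artifacts (inputs are assumed
motion-corrected), photon shot-noise statistics, spatially correlated
noise, neuropil contamination, overlapping cell footprints, or
non-stationary background rates.

## Determinism and logging

Every stochastic step takes an explicit seed; fixed seeds give
bit-identical outputs (verified for JSON artifacts). Parameter choices
and every exclusion (zero-variance pixels, invalid baselines, zero
pre-treatment means) are recorded in a run log written alongside results.

## Limitations

- Exact-recovery guarantees hold only for the impulse-rendered,
  noise-free generator configuration; realistic kernels bias sizes and
  durations upward by the decay-tail factor.
- Event detection cannot separate same-neuron events closer than one
  template length, and onsets are only as precise as the best-correlated
  start frame under noise.
- The ensemble member definition (any neuron with an event in the
  significant window) admits coincidental background members; at
  background rate 0.002 an injected 10-member ensemble is typically
  recovered with all members plus occasional extras.
- The shuffle null assumes exchangeable event times within neuron;
  strong slow rate modulation would require the circular-shift scheme or
  a blocked shuffle.
- Statistics treat fish as independent units; no hierarchical modeling
  of within-fish correlation beyond epoch averaging.
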