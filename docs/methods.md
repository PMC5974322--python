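# Methods

This note documents the models implemented in `boutonscope`, the default
parameter values and why they were chosen, what the synthetic generator
does and does not capture, and the numerical choices that matter for
reproducing results.

## Synthetic scene and movie generator

`synthetic.generate_scene` builds a field of axonal arbors as smooth
random polylines, places boutons along each arbor as a Poisson process in
arc length, and gives every bouton a binary spike train derived from its
parent axon's train by independent thinning (per-bouton release
probability drawn from U(0.7, 1)). This encodes the central biological
structure: boutons of one axon share the parent neuron's spikes, so their
calcium traces are strongly correlated, while boutons of different axons
are independent.

Spike trains are convolved with a difference-of-exponentials calcium
kernel (`spikes_to_calcium`, rise 0.18 s, decay 1.8 s, normalized to unit
peak) approximating a slow genetically encoded indicator at cortical
temperatures. `render_movie` draws each bouton as a Gaussian spot
(`psf_fwhm_um`, default 1.5 µm — a bouton of ~1 µm seen through a ~1 µm
lateral PSF), scales it by `bouton_amp` times the calcium trace on top of
a flat `baseline`, optionally adds a smooth neuropil field driven by
low-pass-filtered population activity, and finally adds gamma noise (see
below).

Default study conditions (fixed in `benchmarks`):

| parameter | default | rationale |
|---|---|---|
| `um_per_px` | 1.0 | camera pixel comparable to bouton size; the regime where detection is non-trivial |
| `fps` 60 → resampled 6 Hz | matches the acquisition-then-10-frame-averaging workflow |
| `baseline` | 20 | counts scale giving realistic shot-noise-to-signal ratios at NR ≈ 0.5–5 |
| `bouton_amp` | 30 | peak transient ≈ 1.5x baseline, typical for strong boutons |
| `nr` (render) | 0.5 | modest intrinsic noise floor of the reference modality |
| bouton density | 110–180 / mm | within the observed range for thalamocortical arbors |
| event rate | 40 / min (5–80 heterogeneous in the degradation movie) | bracketing reported bouton event rates |

Realism and limitations:

* Boutons are ideal Gaussians with static positions; no axial drift,
  bleaching, or slow baseline wander.
* The neuropil field is rank-1-like (one smooth spatial profile times one
  temporal signal). Extraction assumes a rank-1 background, so movies with
  strongly spatially structured neuropil violate that assumption and
  produce spurious components; the standard benchmarks therefore render
  with `neuropil_amp = 0` and neuropil handling is validated separately on
  constructed trace bundles.
* Quiet boutons are invisible (zero resting contrast). Real movies carry
  static texture (vessels, resting structures) that anchors rigid
  registration; synthetic movies intended for registration tests must add
  static landmarks explicitly.
* Spike trains are Bernoulli per frame (no bursts or refractoriness).

`generate_bead_phantom` renders sub-resolution beads in a scattering gel:
lateral size combines bead diameter (σ ≈ d/4) with a depth-growing optical
blur, intensity decays exponentially with depth, and a diffuse background
proportional to out-of-focus bead mass is either kept (widefield mode) or
suppressed by a pinhole-rejection factor (confocal mode).

## Optics arithmetic

`optics` is pure arithmetic over an instrument geometry: maximum frame
rate = (disk rpm / 60) / scan fraction (default 10,000 rpm and 1/3 of a
rotation per field → 500 fps); pinhole spacing at the focal plane = disk
spacing / magnification (500 µm / 13 → 38.46 µm); pixel size = field of
view / sensor pixels; axial depth correction = n_specimen / n_immersion
(1.33 for water via an air objective); data rate = W x H x bytes x fps
(5310 x 4320 x 2 B x 60 fps ≈ 9.91 TB/hour). Full precision is always
returned; `fmt` handles display rounding.

## PSF metrics

`fit_gaussian_fwhm` fits offset + amplitude Gaussians by least squares
with moment-based initialization; FWHM = 2 sqrt(2 ln 2) σ.
`bead_fwhm_3d` refines the bead center by center-of-mass of top-decile
intensities, then fits the X and Z lines through the maximum; z
coordinates are pre-scaled by the z step times the refractive-index depth
correction. Signal-to-background is peak over surround mean in a 30 µm
square excluding a central 10 µm circle, and `sbr_depth_profile` compares
two imaging modes per depth with an exact two-sample rank-sum test.

## ROI extraction (`roi.extract_rois`)

Constrained NMF on the resampled, detrended movie `Y ≈ A C + b f`:

1. **Seeding.** Iteratively select the pixel maximizing local temporal
   energy, seed a component in a radius-6 patch, and subtract. Seeding
   stops when the candidate's *kinetics-matched peak SNR* falls below
   `min_snr`: the detection statistic is the peak of a 0.5-s moving
   average (minus its 8th percentile), times sqrt(window), over the raw
   noise SD. Indicator transients persist for seconds while camera noise
   is frame-independent, so averaging at the indicator timescale separates
   them maximally; this is a matched-filter argument, not a tuned
   constant.
2. **Alternating HALS.** Non-negative hierarchical least-squares updates
   of spatial components (restricted to their dilated support), temporal
   components, and a rank-1 background. The residual norm is checked to be
   non-increasing across alternations.
3. **Denoising and events.** Each trace is denoised under an AR(1) model
   (coefficient from the lag-1/lag-0 autocovariance) and deconvolved into
   a non-negative event series; events are thresholded at 3x the noise SD
   (estimated from the median absolute successive difference, robust to
   transients).
4. **Screening and merging.** Components below `min_snr` (same
   kinetics-matched statistic) are discarded; components closer than 2 px
   with trace correlation > 0.8 are merged.

Defaults: `min_snr = 5` (detection-theory scale: a 5-sigma matched-filter
peak), `max_components = 50`, resample target 6 Hz. Raw per-ROI traces
(`roi_fluorescence`) are footprint-weighted averages normalized by the
footprint sum, keeping them in raw intensity units, invariant to the
arbitrary HALS footprint scale, and directly comparable to surround pixel
means.

Rigid registration uses phase cross-correlation against the temporal mean
(subpixel upsampling factor 10). ΔF/F uses an 8th-percentile baseline,
either global or sliding in a ±15 s window.

## Neuropil decontamination (`neuropil`)

Model: `F_roi = F_true + r x F_np`, with `F_np` the mean of an annulus
within 2 µm of the ROI support (support excluded). The slope is estimated
per ROI by IRLS robust regression (Tukey bisquare, c = 4.685) after
excluding frames where `F_roi` exceeds its mean + 2 SD (transient-active
frames would otherwise dominate the fit). Two validity guards follow from
the model, not from tuning:

* a slope statistically indistinguishable from zero (|slope| < 2 SE)
  means the contamination is unidentifiable on this trace → excluded;
* `r` is a mixing fraction, so only slopes in [0, 1] enter the field
  median. Slopes far above 1 occur when the surround barely fluctuates
  and the regression locks onto the ROI's own PSF skirt bleeding into the
  annulus; pooling them would corrupt every trace. If no ROI yields a
  physical slope, `r = 0` and traces pass through unchanged.

The field median `r` is applied uniformly: `F_true = F_roi - r x F_np`,
then baseline and ΔF/F.

## Gamma pixel-noise model (`noise`)

Pixel intensities are modelled as gamma-distributed with shape `k` and
per-pixel scale θ = sqrt(NR x mean / k); the added-noise variance is then
exactly NR x mean (the kθ² identity), and the added mean is kθ =
sqrt(k NR mean). `k` is fixed at 2.57 for injection; fitting per-pixel
`k`/θ is available for diagnostics. NR is estimated by ordinary
least-squares regression of pixel variance on pixel mean over 100 randomly
sampled non-vessel pixels (vessels = darkest 5% of temporal means), after
normalizing by the variance of temporal means. The paper-faithful mode
regresses on the *observed* mean; a diagnostic mode regresses on the
known pre-noise mean, because injected noise shifts the observed mean by
kθ and would bias the slope.

`degradation_study` injects noise at increasing NR, re-extracts, matches
ROIs to the clean reference by center distance ≤ 3 px, and reports: the
ROI count ratio; the event retention of matched ROIs (their post-noise
event count over the same ROIs' clean event count — ROI loss and per-ROI
event loss are separate effects, and unmatched spurious detections must
not inflate the numerator); and the mean correlation of matched event
series. ROIs still detected at the reference NR (3.71) are flagged
robust, and `robust_roi_comparison` compares per-ROI metric distributions
between all and robust ROIs with an exact two-sample KS statistic.

## Correlation and overlap (`correlation`)

Seed-pixel maps are Pearson correlations of every pixel with a seed pixel
after 2x2 spatial and 10-frame temporal mean-binning (10,000 frames → 1,000
time points). Because boutons of one axon share spikes, the map traces
the arbor as a beaded curve; `peak_density_along_path` samples the map
along a polyline (bilinear interpolation) and counts prominence-based
peaks per millimetre. `pairwise_correlation` returns the ROI correlation
matrix, a 0.02-wide-bin histogram and an average-linkage cluster order.
`plane_overlap_analysis` counts cross-plane ROI pairs whose shared pixel
fraction (relative to the smaller ROI) exceeds 0.5, excluding pairs whose
temporal correlation exceeds 0.6 (same axon seen twice), and reports the
overlapping/non-overlapping ratio.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; derived seeds are drawn below 2^31. Re-running any
  pipeline or benchmark with the same seed is bit-reproducible.
* Movies are float32 in memory (halves the footprint of long renders);
  statistics are computed in float64.
* Noise SD of traces uses the median absolute successive difference /
  sqrt(2), robust to sparse transients.
* Statistical comparisons that back acceptance checks use exact methods
  (exact rank-sum enumeration, KS statistic verified against brute-force
  CDF supremum) rather than asymptotic approximations where sample sizes
  are small.
* Benchmark durations are set by identifiability, not convenience: the
  contamination bundles use 6,000 frames because the slow neuropil leaves
  ~T/35 independent samples, and the two-axon scene runs 240 s so the
  chance-correlation null (SD ~0.06) is cleanly separable from same-axon
  coupling.
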