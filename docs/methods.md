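# Methods

## The measurement model

A coil-QA acquisition consists of paired magnitude images per axial slice: a
*Signal* image of a homogeneous cylindrical phantom and a *Noise* image
acquired with the RF transmitter off, so only receiver-chain noise is
recorded. The default geometry is 18 slices of 10 mm thickness with 100% gap
(center-to-center spacing 20 mm), symmetric about isocenter, so the slice
centers run −170 … +170 mm and span 34 cm; the field of view is 300 mm at
matrix 256 (pixel spacing 1.171875 mm) with a 135 mm phantom.

Combined-element analysis segments the phantom per slice, measures the
Signal-ROI mean and Noise-ROI SD inside a circle of 90% of the phantom
width, and reports SNR = correction · mean/SD and percent image uniformity
PIU = 100·(1 − (S_max−S_min)/(S_max+S_min)). Uncombined analysis measures,
per element and slice, the noise SD inside the ROI transferred from the
sum-of-squares combined by-product and the mean signal in a 5 px radius ROI
at the in-phantom peak of the 10 px box-smoothed Signal image.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| ROI diameter fraction | 0.90 | – | large fraction suits the narrow (13.5 cm) phantom |
| SNR correction | 1.0 | – | plain mean/SD ratio; 0.655 converts a Rayleigh noise-image SD to the equivalent Gaussian σ. Switching rescales all baselines, so it is a prominent config item |
| peak ROI radius | 5 | px | 5.86 mm at the default pixel spacing; proportional to phantom cross-section |
| smoothing window | 10 | px | box filter; stabilizes the peak location against pixel noise |
| peak-summary slices | ±110/130/150 | mm | locations of maximal element SNR; sign from the group's superior (…P) / inferior (…S) position, matched to the nearest measured slice within 1 mm |
| warn / fail (sd) | 2σ / 3σ | – | two-sided; sample SD of the accepted baseline |
| warn / fail (percent) | 5% / 10% | of mean | selected automatically for baselines with <10 datapoints |
| position floor | 5 | SNR | elements never exceeding it are reported "undetectable" |

## Synthetic generator

The generator emulates the *statistical* structure the analysis assumes, not
the physics that produces it (no Bloch, coil-field or k-space simulation):

- **Magnitude noise.** Rayleigh by default (two i.i.d. Gaussian receiver
  channels, σ = `base_sigma`); Signal-image pixels are then Rician around the
  noise-free amplitude. A `gaussian-magnitude` option (|a + N(0,σ)|) exists
  because its moments are simpler for exact tests. Noise is boosted by a
  multiplicative step (×1.3 default) for |z| ≤ 30 mm, reproducing the
  elevated noise of the central slices of a vertically split magnet. A step
  is the simplest model with that signature; its consequence is that
  synthetic SNR peaks at the signal peak (±90 mm) rather than slightly
  beyond it (±130 mm) as on a scanner whose noise decays continuously with
  |z|.
- **Combined series.** In-phantom intensity is a slice-wise constant from an
  axial profile, 650·exp(−((z∓90)/280)²) for torso/head-neck, optionally
  modulated in-plane by a vertical gradient (±18% across the phantom) for
  unfiltered surface-coil images. With `base_sigma` = 22 this places SNR at
  ≈45 near the peak, ≈31 at isocenter and ≈19 at the far end, and uniformity
  at ≈70–87% — the ranges a well-functioning torso coil set shows. The
  prescan-normalization condition is emulated by replacing the axial shape
  with a body-coil-like bell centered at isocenter and dropping the in-plane
  gradient; it exists so both filter conditions have fixtures, not as a model
  of the filter. The body-coil preset uses a taller bell (1050 a.u.) with 5×
  the noise.
- **Elements.** Sensitivity is separable: exponential in-plane falloff
  (decay 45 mm) from a point on the phantom rim at the element's angle,
  times a Gaussian axial profile (width 110 mm) centered at ±95 mm. Twelve
  channels in four groups of three (VAP/VAS bottom, VPP/VPS top; P = superior,
  S = inferior). `sensitivity_scale` = 550 and `noise_sigma` = 10 yield peak
  element SNR ≈60–75 and maximum signal ≈550 a.u. The head/neck preset marks
  VAP3/VPP3 as physically absent: zero sensitivity, σ = 3 receiver noise,
  which reproduces their observed <3 SNR signature.
- **Faults.** `dead`: the element's signal is a flat 10 a.u. residual across
  the phantom and all slices, and its noise triples — this lands the measured
  peak SNR at ≈2.3 without being fit to any target. `noisy`: noise ×1.25,
  emulating slow element degradation (~20% SNR loss).
- **Quantization.** Pixels are clipped at 0, rounded and stored as uint16.
  Rounding adds variance 1/12, i.e. <0.1% of the noise variance at the
  default σ, so analytic ground-truth moments (exact Rician/Rayleigh means
  and SDs via `scipy.stats`) ignore it.

What the generator does **not** emulate: structured artifacts (ghosting,
spikes), spatial noise correlation, B0/B1 inhomogeneity, slice cross-talk,
inter-scan setup variability. Passing tests therefore demonstrate that the
estimators and decision rules behave correctly under the assumed statistical
model, not that the pipeline is robust to every real-world artifact.

## Numerical choices

- Thresholding uses Otsu on the full image (scale-invariant); a
  fraction-of-maximum alternative is configurable. Holes are filled and the
  largest connected component kept before measuring extents.
- Phantom center/width are the midpoint/extent of the component's axis-aligned
  bounding box; width = c_max − c_min + 1 pixels.
- The noise SD is the sample SD (n−1). A noise SD of exactly zero raises an
  error (a corrupt or empty Noise image) rather than returning infinite SNR.
- The box filter uses replicate borders; an even window is anchored one pixel
  toward the top-left (the window at pixel *i* covers rows *i*−w/2 …
  *i*+w/2−1). Peak ties are broken by smallest (row, col) lexicographically.
- The peak search is restricted to the phantom mask eroded by a disc of the
  ROI radius, guaranteeing ROI containment for any input rather than relying
  on smoothing alone.
- Baseline statistics use the sample SD; a zero-SD baseline passes only an
  exactly equal measurement. Decisions are two-sided: drops indicate faults,
  flares indicate instability. A warn-level measurement is accepted into the
  baseline by default (only fails are excluded), overridable per run.
- Overall coil verdict: fail if any element fails or more than half the
  slices fail on one combined metric; otherwise the worst per-metric status.

## Design choices where the design was open

- Each slice is segmented independently (rather than reusing one geometry per
  series): robust to slight phantom tilt, at the cost of sub-pixel ROI
  jitter between slices.
- The element label is read from the Receive Coil Name tag, then an optional
  configurable private tag, then a regex on SeriesDescription — the tag
  layout varies between scanner software versions.
- Signal/Noise classification uses the larger-maximum rule with acquisition
  order (InstanceNumber) as tie-break.
- The review "video" is a numbered PNG frame sequence per element; portable
  and diff-able, with MP4 assembly left to external tools.

## Problem sizes used in validation

The test suite and the acceptance script validate at the default acquisition
size (18 slices × 256² px, 12 elements): estimator recovery uses 100
generated series; the fault-detection study uses a 10-run healthy baseline
and 50 evaluation runs with an injected dead element; brute-force oracle
comparisons use 20 random small images per operation. Scaled-down stacks
(fewer slices, smaller matrices) are used where only structural behavior is
exercised.

## Known limitations

- Axial acquisitions only; no reorientation is performed.
- The step noise model shifts the synthetic SNR peak to the signal peak (see
  above); tests assert the SNR *minimum* location, which is unaffected.
- The in-plane element sensitivity shape is a plausible guess constrained
  only by peak locations; absolute per-element signal levels are not
  calibrated to any particular hardware.
- The baseline engine implements fixed 2σ/3σ and 5%/10% thresholds; no
  EWMA/CUSUM-style control charting.
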