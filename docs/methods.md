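# Methods

## Signal model

A resting sheep's breathing displaces the thorax boundary quasi-periodically
at 0.33–0.67 Hz (19.8–40.2 breaths/min). Any surface point inside the
thorax region of interest (ROI) therefore moves along a trajectory whose
x/y components contain a common narrow-band oscillation plus broadband
tracking noise, slow posture drift and, at night, sensor noise. The
pipeline treats RR extraction as blind source separation over many such
trajectories followed by windowed dominant-frequency estimation:

- first differences of the trajectories suppress position offsets and slow
  drift (a first difference is a high-pass with zero DC gain), so the
  band-pass + PCA stage sees approximately stationary signals;
- PCA over the stacked, mean-centred dx/dy derivative rows concentrates the
  coherent breathing motion — shared by most points — into the leading
  component, while incoherent tracking noise spreads over the tail;
- within a 10 s window the rate is assumed locally constant, so the
  dominant in-band FFT peak estimates it; sliding the window one frame at a
  time yields an RR time series at the video frame rate.

Assumptions: the animal is at rest (gross locomotion is excluded upstream
by manual selection or, in synthetic data, never generated); the mask
isolates exactly one animal; the frame rate is known and at least twice
the band's upper edge (satisfied at both 10 and 20 fps).

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| detector max points N | 200 | corners | enough trajectories for stable PCA on a thorax-sized ROI |
| FAST contrast threshold | 2 | gray levels | wool texture after CLAHE is low-contrast; a permissive threshold keeps the ROI densely seeded |
| bucketing cell | 4×4 | px | at most one corner per cell spreads points over the ROI instead of clustering on the sharpest speckle |
| LK window / levels / iters / eps | 21 px / 3 / 20 / 0.01 px | — | common pyramidal-LK operating point; window large enough to average sensor noise, pyramid tolerant of occasional larger shifts |
| band-pass | 0.33–0.67 Hz, order 2, zero-phase | — | resting ovine respiratory band; forward–backward application avoids phase lag in the windowed estimates |
| PCA components inspected | 6 | — | breathing dominates the first component in practice; `best_inband` scans the first six |
| RR window | 10 | s | 3–6 breath cycles per window: enough for a sharp peak, short enough to follow rate changes |
| FFT zero-padding | 4096 | samples | frequency step 0.29 bpm at 20 fps (0.15 at 10 fps), well below the ±1 bpm validation tolerance |
| smoothing kernel | 10 | s | one analysis window; longer kernels lag rate changes |
| certainty threshold | > 0.75 | — | strict "above"; detections at exactly 0.75 are rejected |
| box-IoU validity threshold | > 0.80 | — | strict, as above |

All of these surface in `PipelineConfig` (groups `tracker.*`, `filter.*`,
`rr.*`, `roi.*`) and as YAML/CLI overrides.

## Synthetic scenes

`SyntheticSpec` renders a speckle-textured ellipse (wool-like, Gaussian-
smoothed uniform noise) on a dark background. Each frame warps the texture
radially so the boundary sits at `1 + A(x)·sin(2πft)/R(θ)` of its resting
elliptical radius; `A(x)` tapers linearly along the long axis from
`amplitude_px` at the abdominal end to `amplitude_gradient · amplitude_px`
at the cranial end, reproducing the abdominal-dominant signal strength seen
in recumbent animals. Per-frame Gaussian sensor noise and optional linear
illumination drift are added; NIR scenes are single-channel with lower
texture contrast and a higher default noise floor (4 vs 2 gray levels) to
mimic night footage. One integer seed determines the scene bitwise.

What the generator does *not* emulate: posture shifts and limb movement,
occlusion, perspective foreshortening, breathing-rate variability within a
scene, wool deformation, and segmentation errors (masks are exact). Passing
the synthetic validation therefore demonstrates the signal-processing chain
recovers a known periodic motion under realistic noise — not robustness to
gross motion artefacts, which upstream rest-selection must handle.

Default problem sizes in the tests and the acceptance script — 20–30 s
scenes at 120×160 px — were chosen as the smallest scenes that hold several
hundred analysis windows and a fully populated 200-point tracker; recovery
results were indistinguishable on larger canvases.

## Numerical and design choices

- **Band edges in Hz.** The pass band is implemented as 0.33–0.67 Hz
  (= 19.8–40.2 bpm); all emitted RR values are clamped to this band by
  construction of the in-band argmax.
- **CLAHE conventions.** `enhance(tile=(8,8), clip=2.0)` follows the
  common CV convention: `tile` is the grid of contextual blocks and `clip`
  a multiple of the uniform histogram height; internally the clip limit is
  rescaled to scikit-image's [0, 1] fraction as `clip/256`. A constant
  image is returned unchanged.
- **Detection.** FAST-9 response via `skimage.feature.corner_fast`;
  grid bucketing keeps the strongest corner per cell, ties broken toward
  the smaller pixel index, then the global top-N by response.
- **Tracking.** Sparse pyramidal Lucas–Kanade written against scipy/numba
  primitives: per level, the template window and its gradients come from
  the earlier frame, and Newton iterations minimise the SSD against the
  later frame. Points are marked invalid — permanently — when the window
  leaves the image, the 2×2 normal matrix is near-singular, or the flow
  diverges. Positions are chained frame-to-frame (no anchoring to frame 0,
  no re-seeding, no interpolation of lost points).
- **PCA input orientation.** Variables are the 2M band-passed derivative
  rows, observations the T−1 time samples; component scores over time are
  the candidate respiratory signals. The selected component is band-passed
  once more (idempotent in-band; removes residual out-of-band leakage).
- **Peak picking.** Global argmax of the zero-padded magnitude spectrum
  restricted to the closed band; ties resolve to the lower frequency
  (first index). Each window is linearly detrended before padding.
- **Smoothing.** Edge-normalised moving average: partial windows at the
  series borders are divided by their actual overlap, so output length is
  preserved and constant series are fixed points. This estimator is
  row-stochastic but not column-stochastic, so the series mean is *not*
  exactly conserved near the edges — by design, the borders stay unbiased
  at the cost of exact mean conservation.
- **Region splitting.** The mask's axis-aligned bounding box is cut
  perpendicular to its longer side into three equal-width bands
  (boundaries at rounded thirds); principal-axis rotation was rejected as
  over-engineering for recumbent animals. Which end is abdominal is a
  caller flag (`r1_left` default).
- **Agreement statistics.** Relative error is normalised by the expert
  reference; standard deviations use ddof = 1; Bland–Altman differences
  are reference − video with limits at ±1.96 SD; everything is computed at
  full precision and rounded only for display.
- **Degenerate inputs.** Empty masks, all-below-threshold detections,
  signals shorter than one window, and total tracking loss raise typed
  exceptions (`DegenerateInputError`, `NoValidInstanceError`,
  `TrackingCollapseError`); the CLI maps the latter two to exit codes 2
  and 3.

## Known limitations

- No re-detection: a long occlusion or lighting transient that invalidates
  all points aborts the instance rather than recovering.
- Rates outside 19.8–40.2 bpm (panting, bradypnoea) are unobservable by
  construction; widening the band admits more motion artefacts.
- The window/kernel pair (10 s + 10 s) smears rate transitions over about
  20 s; the per-window series is available unsmoothed for faster dynamics.
- Segmentation quality is consumed, not produced: mask errors propagate
  directly into the trajectories.
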