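# Methods

## The measurement problem

A nuclear-envelope rupture empties part of a nucleus's NLS-tagged reporter
into the cytoplasm within one acquisition interval; the signal then
recovers over tens of minutes as the envelope reseals and the reporter is
re-imported. Detecting these events from the NLS channel alone is fragile:
long recoveries break track assignment, and transient focus loss in mobile
cells dims the nuclear signal in a way that mimics a rupture. The method
therefore measures, per tracked nucleus, the ratio of the mean intensity of
a chromatin-bound reference (H2B) to the mean NLS reporter intensity. Both
channels scale identically under illumination drift and focus dips, so the
ratio cancels those exactly, while a rupture moves only the reporter.

## Detection statistic and event calls

The statistic is the multiplicative frame-to-frame fold change of the ratio
(ΔH/N): `dhn(t) = ratio(t)/ratio(t−1)`, undefined at the first frame. A
multiplicative (not additive) differencing makes the fixed threshold 1.2 —
a 20% step increase of the ratio, i.e. a ~17% one-frame reporter drop at
constant reference — unit-free and exactly invariant to any positive global
per-frame scaling of both channels. Maximal runs of consecutive
supra-threshold frames are merged into one event anchored at the run's
first frame; a subsequent event requires at least one sub-threshold frame
between runs. Two quality gates veto artifact calls: onsets on
gap-interpolated frames, and onsets coinciding with an abrupt segmented-
area change (> 35% in one frame) — a rupture moves intensity, not area, so
a concurrent area jump marks a segmentation failure (typically two touching
nuclei merging into one mask or splitting again). A characterized event
whose measured extent stays below 0.1 — far below the ~0.17 drop implied by
a genuine 1.2 ratio step — is likewise discarded as internally
inconsistent.

## Event characterization

All amplitudes are read from the normalized but *unsmoothed* reporter
series (kinetics must not be buffered by smoothing):

* **baseline** — mean reporter level over the 5 usable frames before onset,
  excluding frames inside an earlier event's onset-to-recovery interval;
  with fewer than 2 usable frames the event is kept but uncharacterized.
* **minimum** — lowest reporter level between onset and the next event (or
  track end).
* **extent** — (baseline − minimum)/baseline, the severity of the rupture.
* **complete** — the reporter returns to ≥ 95% of baseline ("restored
  completely") before the next event or track end.
* **T_r** — for complete events, the time from onset to the first upward
  crossing of (baseline + minimum)/2, linearly interpolated between frames.
  Crossing and completeness are evaluated on a width-3 running median of
  the reporter, which is the identity on monotone stretches (so it cannot
  bias a clean recovery) but suppresses single-frame spikes from residual
  segmentation glitches. T_r is referenced to the event **onset** — the
  anchor used for ensemble synchronization — not to the minimum; for an
  abrupt drop the two coincide, and the choice is configurable in spirit by
  subtracting `minimum_frame − onset_frame` intervals.

For a single-exponential recovery `N(t) = B·(1 − d·e^{−t/τ})` the truth is
closed-form: extent = d and T_r = τ·ln 2. The implementation reproduces
both on noiseless traces to ≤ 0.08 min and exactly, respectively, across
τ ∈ [5, 120] min at a 2-min frame interval.

## Segmentation pathway

Detection and measurement are deliberately decoupled:

* **Normalization** (measurement pathway): each frame is scaled by one
  global factor so that a robust brightness statistic — the median of
  pixels above a triangle-method background threshold, insensitive to how
  much of the field is covered by cells — matches frame 0, per channel.
  This cancels temporal illumination variation while preserving all
  within-frame structure and cross-channel ratios.
* **Local contrast enhancement** (detection pathway only): tile-based
  adaptive histogram equalization (tile ≈ 2× nucleus diameter, clip limit
  0.01) levels per-cell expression differences so dim cells are found; it
  never touches measured intensities.
* **Smoothing**: separable Gaussian in y, x and frame. The temporal SD is
  given in minutes and hard-capped at 10 min — beyond that, moving nuclei
  smear into unsegmentable streaks. The reference channel defaults to
  lateral-only smoothing; NLS-only (single-marker) operation forces ≥ 4 min
  temporal smoothing because the segmented channel itself dims at every
  rupture.
* **Blob detection**: scale-normalized Laplacian of Gaussian (σ ≈ nucleus
  radius/√2), binarized with Otsu's threshold floored at 2 robust (MAD)
  noise SDs of the response — Otsu alone splits pure noise near its median
  on structure-free frames. Regions below the minimum area or whose peak
  response stays below 5 noise SDs are discarded, so empty frames yield
  zero detections rather than noise blobs.
* **Conditional watershed**: objects larger than 1.5× the frame's median
  object area, or insufficiently solid (solidity < 0.9), are split
  candidates. Seeds are the two strongest distance-transform maxima (shape
  information is more stable than intensity for touching near-convex
  blobs); a split is accepted only if both children reach the minimum area
  and the LoG-response saddle along the split boundary stays below 0.9× the
  dimmer seed's peak — a genuine two-nucleus neck, not a texture dip.
* **Measurement**: per-region area, centroid, per-channel means on the
  normalized-unsmoothed stack, and circularity 4πA/P². The perimeter comes
  from the marching-squares contour smoothed by a circular Gaussian (σ = 2
  contour samples): the raw staircase overestimates curved outlines by
  ~5%, while the smoothed contour measures a rasterized r = 50 disk within
  0.2% of 2πr and a 2:1 ellipse within 0.01 of its Ramanujan-formula
  circularity. The residual known bias is corner rounding on straight-edged
  shapes (a square measures ~0.82 vs π/4 ≈ 0.785).

## Tracking

Nearest-neighbor linking, resolved greedily by ascending centroid distance
(equivalent to the Hungarian optimum on these sparse scenes), ties broken
by lower track id; the outcome is invariant to detection order within a
frame. A track end may bridge up to 5 missed frames with a displacement
budget growing linearly with the gap (`max_displacement × (gap+1)`,
default 40 px); bridged frames are linearly interpolated and flagged so
they can never anchor an event. Tracks shorter than 60 min are removed
(strict `<`, so a track of exactly 60 min survives). Frames whose
segmented area leaves [0.6, 1.4]× the track's median area are treated the
same way as gaps — they are measurements of a wrong mask (merge/fragment),
not of the nucleus.

## Population statistics

* **Dip test**: Hartigan's dip — the minimal sup-norm distance between the
  empirical CDF and any unimodal CDF — computed with the iterative greatest
  convex minorant / least concave majorant algorithm. The implementation
  was validated against an exact linear-programming oracle (the fixed-mode
  minimization is an LP; the oracle enumerates data-point modes with an
  optional atom at the mode plus a grid of in-gap modes) on hundreds of
  random samples including heavily tied ones, agreeing to ~1e-12. p-values
  come from `n_boot` (default 2000) uniform null samples of the same size;
  the uniform is Hartigan's calibration choice as the least favorable
  unimodal law. Note the dip is invariant under affine transforms of the
  sample but *not* under general monotone transforms — nonlinear maps do
  not preserve the convex/concave structure of the unimodal class.
* **Mixture fit**: unconstrained two-component normal mixture on raw
  minutes (matching the mean ± SD convention for fast ≈ 13 ± 6 and slow ≈
  67 ± 43 min populations), fitted by EM from the best of `n_starts` seeded
  initializations, components reported mean-ascending. The per-iteration
  log-likelihood is recorded and checked to be non-decreasing; component
  SDs are floored at 1e-3 of the sample SD and a floored fit is flagged
  degenerate. Percentile bootstrap CIs (default 200 resamples) are
  available for the component parameters. Truncation of halftimes at zero
  is ignored during fitting.
* **Tipping point**: the halftime with equal posterior membership
  probability, i.e. the root of w₁φ₁(x) = w₂φ₂(x) between the two means
  (log-quadratic, solved in closed form). If no root falls between the
  means (extreme variance ratios) the nearest crossing is returned with a
  warning. For the fast/slow convention a fixed boundary of 30 min
  classifies events into the two groups for ensemble curves.
* **Extent-vs-halftime**: ordinary least squares with R² = 1 − SSres/SStot
  and a normal-theory 99% confidence band for plotting.

## Synthetic recordings and what they do (not) show

The generator emulates the acquisition geometry (2-min frame interval,
single confocal section, 20×) with: star-convex nuclei (radial low-order
Fourier perturbation of an ellipse) whose boundary wobbles by an AR(1)
process scaled by `deformation_amplitude` (0 = rigid disks); a reflected
random walk with pairwise exclusion — nuclei sit in different cells and
cannot interpenetrate, so a step that would overlap two outlines is
rejected for that frame (residual touching still occurs and exercises the
watershed); per-cell lognormal expression (CV 0.2 per channel); additive
Gaussian read noise (default SNR = signal/noise-SD = 10) with optional
Poisson shot noise; global per-frame illumination factors multiplying both
channels; and scripted ruptures with instantaneous drop, single-exponential
recovery (chosen because it yields a closed-form halftime oracle), optional
transient area contraction (area ×(1 − c·e^{−t/τ})) and a focal H2B
brightening spot emulating post-rupture local chromatin condensation.

Not modeled: photobleaching, 3D structure, cell division and death,
mechanistic import kinetics, and spatially structured background. Passing
the benchmarks therefore demonstrates the *algorithmic* correctness and the
claimed invariances of the pipeline under controlled, realistic-scale
conditions — not performance on any particular microscope's data, where
point-spread, debris and curation effects differ.

## Validation study conditions (problem sizes)

* **Detector operating point**: 20 movies (10 nuclei, 150 frames, 256²,
  SNR 10), ~55% of nuclei carrying 1–2 scripted ruptures with drop ∈
  [0.25, 0.6] and τ ∈ [10, 60] min; scored by greedy matching of called
  onsets to scripted onsets (±2 frames) on the same nucleus. Plus 5 control
  movies whose only dynamics are smooth global dips of both channels down
  to 50% brightness — these must produce zero calls.
* **Kinetics oracle**: 47 noiseless traces, τ ∈ [5, 120] min, drop 0.5.
* **Tracking**: frame-to-frame identity agreement vs ground truth over the
  20 detector movies (~30k links), and a dropout check in which one
  detection per nucleus is deleted from an ideal detection table.
* **Population cohorts**: 50 cohorts of 45 nuclei / 160 frames / 320², one
  rupture per nucleus with halftime drawn from a two-component normal
  mixture (means 13 and 67 min; SDs 3 and 10 min; equal weights) truncated
  to [5, 22] and [40, 85] min so every recovery can complete within the
  320-min recording with onsets at 16–28 min. A cohort counts as a success
  when both fitted component means fall within 20% of the cohort's realized
  scripted means *and* the dip test rejects unimodality at p < 0.05 (dip
  n_boot = 300 here; the component SDs and the ~45 events per cohort were
  sized a priori so the dip test has adequate power at this separation).
  Using the realized (truncated) scripted means as the reference avoids
  penalizing the fit for the scripted truncation itself.

## Numerical choices and degenerate inputs

* Time is minutes throughout; frame indices and pixel coordinates are
  0-based (y, x); labels are 8-connected.
* Linking ties are broken by (distance, track id, sorted position);
  deterministic for fixed input.
* An all-zero frame aborts normalization with the frame named; a constant
  frame normalizes to factor 1.
* Empty detection tables yield empty track sets; an empty event list yields
  an empty ensemble; mixture fitting requires n ≥ 10 and a non-constant
  sample; the dip test requires n ≥ 4.
* All randomness (generator, dip bootstrap, EM starts, benchmarks) flows
  from explicit integer seeds; identical seed + config reproduce outputs
  byte-for-byte.

## Known limitations

* The 2D greedy linker has no motion model; it is adequate at the default
  step-SD/displacement ratio but will swap identities in dense, fast
  scenes a Kalman/JPDA tracker would handle.
* Extent is measured on raw means including background, so at image level
  it underestimates the scripted nuclear drop by the background fraction
  (~8% relative at the default contrast); halftimes are unaffected
  (background shifts baseline and minimum equally).
* Incomplete recoveries are excluded from halftime statistics rather than
  treated as censored observations; with long-tailed slow populations this
  biases the slow component downward unless the recording is long enough.
* The conditional watershed separates pairs, not triples; three mutually
  touching nuclei resolve only via the area-outlier gate.
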