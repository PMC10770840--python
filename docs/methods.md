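# Methods

## Problem setting

A camera pointed at a face records three intensity time series — the mean
R, G, B values over a skin region of interest (ROI) per frame. Each is a
candidate remote photoplethysmogram (rPPG). Given a simultaneous contact
photoplethysmogram (cPPG) from a pulse oximeter as ground truth, the
pipeline asks how faithfully each channel reproduces the blood volume
pulse (BVP), in waveform morphology (DTW, Pearson r, RMSE) and in heart
rate (|ΔBPM|), and whether the differences between channels are
statistically significant across subjects (Friedman + Nemenyi).

## Synthetic data model

The generator emulates the *structure* of multi-subject video datasets —
per-subject activities, 60 s per video, a camera at 25/30 Hz and an
oximeter at 60 Hz — not their optics.

**BVP waveform.** A sum of three harmonics of the instantaneous heart
rate, relative amplitudes (1, 0.4, 0.2), amplitude-modulated at a
respiratory frequency (default 0.25 Hz, depth 0.1). The phase is the
integral of the heart-rate profile, so the spectral peak tracks the
configured rate by construction; the overtones make "highest peak" HR
estimation non-trivial rather than tautological. Valid heart rates are
confined to (39, 240) BPM, the band the spectral estimator searches.

**Contact trace.** The BVP sampled at 60 Hz plus white Gaussian sensor
noise (default SD 0.05 relative to unit fundamental amplitude).

**Camera channels.** Each channel is
`baseline + gain·BVP + drift + artifacts + noise` at the camera rate:

* gains (R, G, B) = (0.35, 1.0, 0.6) — encodes the hemoglobin
  absorptivity ordering G > B > R, strong enough to be recoverable at
  n = 12 subjects but deliberately not degenerate (red still correlates
  with the cPPG);
* baselines (120, 110, 100) intensity units — arbitrary DC levels removed
  by normalization/detrending;
* sinusoidal illumination drift (amplitude 2, period 30 s, random phase),
  common to all channels;
* motion artifacts: Poisson-timed exponentially decaying steps
  (τ = 0.5 s), identical across channels (motion is common-mode). Rates
  per second by activity — Resting 0.02, Talking 0.10, Translation 0.15,
  Rotation/Gym 0.30 — with amplitudes 0.5/1.5/2.0/3.0 scaled likewise.
  These magnitudes are simulation choices that encode the qualitative
  claim "motion degrades the signal" as a controllable knob; no
  quantitative noise model per activity exists to calibrate against.
* white sensor noise, SD 0.2 per channel, independent across channels.

Per-scene heart rates are drawn uniformly from 60–90 BPM plus an
activity elevation (0–25 BPM, largest for exercise), constant within a
scene; the generator also supports piecewise-linear HR ramps.

Determinism: every output is a pure function of (parameters, seed);
per-scene seeds derive from the cohort master seed via
`numpy.random.SeedSequence`, and repeated exports are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real video: skin-tone and illumination-spectrum optics,
camera compression and sensor nonlinearity, face/landmark detection
errors, rPPG–cPPG clock skew beyond sub-sample offsets, and non-white
physiological noise. Results on this synthetic cohort validate the
*pipeline machinery* (filters, metrics, rank tests), not any claim about
real skin.

## Preprocessing choices

* **Robust normalization** is `(x − median)/IQR`, the standard robust
  scaler; a zero IQR raises a structured flat-signal error carrying the
  channel/window identity, and the pipeline excludes and logs that unit.
  Normalization is per-video by default (it precedes windowing in the
  chain); per-window scope is available in the configuration.
* **Common rate.** Camera (25/30 Hz) and oximeter (60 Hz) run at
  different rates; comparison requires one grid. Default: linear-
  interpolation resampling of the rPPG up to 60 Hz (identity on the
  cPPG), configurable to the camera rate instead. Linear interpolation is
  exact on degree-1 signals and preserves in-band spectral peaks; the
  sub-sample tail at the trace end is linearly extrapolated so a 60 s
  trace keeps exactly 3600 samples at 60 Hz.
* **Detrending** uses a smoothness-priors (regularized second-difference)
  trend estimate subtracted from the signal, with a linear-detrend
  option. The regularization λ is mesh-dependent: at the 60 Hz common
  rate the default λ = 1000 places the equivalent high-pass corner near
  0.3 Hz — below the 0.65 Hz cardiac band edge (a 1.2 Hz tone is
  preserved to well within 5%) but high enough to remove the generator's
  30 s illumination drift. Substantially smaller λ at this rate would cut
  into the cardiac band itself.
* **Band-pass**: Butterworth of order 6 (as passed to the design routine)
  with 0.65–4 Hz edges, designed in second-order sections and applied
  forward–backward. Zero phase matters because DTW and r compare
  morphology; a causal filter's group delay would penalize all channels
  with a spurious lag.
* **Windows** are cut on the shared timestamp grid starting at t = 0; no
  lag compensation is applied (DTW absorbs residual misalignment). 60 s
  yields exactly six 10-s windows; trailing samples are dropped.

## Metric choices

* **DTW**: local cost |a_i − b_j|, unconstrained monotone steps
  {(1,0), (0,1), (1,1)}, no Sakoe-Chiba band, no path-length
  normalization — raw cumulative cost on equal-duration windows. The
  dynamic program is verified exactly against exhaustive warp-path
  enumeration on short series. Computed on the preprocessed windows as
  produced by the chain (no extra per-window z-scoring).
* **Welch spectra**: Hann taper, 5-s segments (half the window), 50%
  overlap, FFT zero-padded to 4096 points — a 0.0146 Hz ≈ 0.88 BPM grid,
  fine enough that peak-picking rather than binning limits |ΔBPM|. Peak
  search is restricted to 0.65–4 Hz; equal peaks resolve to the lowest
  frequency (deterministic).
* **Reference heart rate**: the generator's ground-truth BPM when
  available (the default), else the spectral estimate from the cPPG
  window — both paths are implemented because real datasets differ in
  whether they ship ground-truth BPM.

## Statistics

Blocks are subjects; when a grouping pools several videos per subject,
their per-video summaries are averaged within the block before ranking.
Ranks use mid-ranks for ties, and the Friedman statistic is the classic
uncorrected form (no tie correction; ties are measure-zero for these
continuous metrics). The Nemenyi q_α comes from a built-in table
(k = 2…10, α ∈ {0.05, 0.10}; Studentized range ÷ √2) with an optional
distribution-based backend for other α. Reported pairwise p-values are
two-sided; no multiplicity correction is applied beyond Nemenyi itself,
which already controls the family-wise error across the three channel
pairs. Calling the post-hoc without a significant Friedman test warns and
flags the result rather than refusing — useful for simulation studies of
the null. Pooling across activities ("all" group) is naive, with no
stratification.

The normalized overview divides each metric's per-channel mean by its
maximum across channels, mapping r to 1 − r first so that lower is
uniformly better; this convention is a documented package choice.

## Problem sizes and numerical notes

The standard simulated study is 12 subjects × 4 activities × 60 s
(power/ranking checks) and 100 equal-gain replicate cohorts of 12
subjects × 1 activity for null specificity; the type-I calibration uses
2000 random 10 × 3 matrices. The DTW-vs-enumeration check uses 500 random
pairs of length ≤ 6 (enumeration is exponential). Degenerate inputs —
flat channels, zero-variance windows, missing rank-matrix cells,
sub-window traces — raise structured errors or are dropped with a logged
reason code, never silently.

## Known limitations

Besides the generator realism caveats above: the trace-file import path
requires uniformly sampled timestamps (no gap handling); the Friedman
approximation is asymptotic in n and conservative for very few subjects;
and the simulated artifact model (decaying steps) is the simplest
morphology-damaging choice, not a fitted motion model.
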