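# Methods

## The model

`speechtrf` implements a forward (encoding) analysis of continuous
speech-in-noise EEG. The EEG at electrode c is modelled as a linear
convolution of the speech envelope s(t) with an unknown impulse response,
the temporal response function (TRF):

    r̂_c(t) = Σ_τ TRF_c(τ) · s(t − τ),   τ ∈ [−200, 500] ms

At the 120 Hz pipeline rate this gives 85 lags in steps of 8.33 ms. The
TRF is the regularized least-squares solution on the lagged design matrix
S (one column per lag, zero-filled at the boundaries):

    TRF = (SᵀS + λI)⁻¹ Sᵀ r,   λ = 2¹⁵ fixed

The penalty is applied literally to the raw normal equations: no
eigenvalue rescaling and no per-condition envelope normalization. A fixed
λ shrinks every condition by the same rule, which is what makes TRF
*amplitudes* comparable across SNR conditions and subjects — the central
requirement of the morphology analysis. The absolute scale of the
coefficients is therefore arbitrary (shrunken) but consistent; all
downstream statistics are either rank-based or calibrated within the same
convention. λ is a config input; no λ search is implemented.

A TRF is interpretable like a slow auditory evoked potential: a negative
deflection near 100 ms (N1) followed by a positive one near 200 ms (P2),
whose amplitudes shrink and latencies grow as the stimulus SNR drops.

## Preprocessing

* EEG: downsample to 120 Hz (polyphase, anti-aliased), then band-pass
  1–10 Hz. The band covers delta and theta and contains the 3.8 Hz
  syllable rate of matrix-test speech.
* Envelope: rectify, power-law compress with exponent 0.6, downsample to
  120 Hz, then the *same* band-pass. The order — compress, resample,
  filter — is fixed and locked by a test.
* The band-pass is a 397-tap Hamming windowed-sinc FIR (order 396,
  type-I linear phase). "Zero phase" is realized as a single pass with
  the integer group delay of 198 samples removed, with zero-padding by
  half the filter length at both ends so output length equals input
  length. A tap count of 397 (rather than 398) is the package's
  convention: a bandpass windowed-sinc design needs an odd tap count for
  a symmetric type-I filter and an integer group delay. Band edges are
  the −6 dB points of the design.
* Artifact removal is a pluggable hook (`none` by default). Synthetic
  data contains no ocular artifacts; real-data users can register an ICA
  or regression cleaner. The hook contract (same shape, labels, rate) is
  enforced.

## Synthetic cohort

The generator produces data with the statistical structure the analysis
assumes, not realistic speech:

* **Stimulus.** Per condition, `duration_s` (default 540 s ≈ 9 min) of
  sentence bursts at the 120 Hz pipeline rate: 8 raised-cosine syllable
  cycles at 3.8 Hz (≈2.1 s, about a five-word matrix sentence) under a
  100 ms onset/offset ramp, separated by silent gaps drawn uniformly
  from 0.9–1.8 s (mean 1.4 s). The envelope is generated directly at
  120 Hz; audio-rate synthesis is unnecessary because every downstream
  stage consumes the 120 Hz envelope.
* **Kernel.** Ground truth TRF = two Gaussians: N1 (−1 a.u. at 100 ms,
  width 22 ms) and P2 (+0.6 a.u. at 200 ms, width 35 ms), support
  clipped to 0–400 ms. At ΔSNR = d, amplitudes scale by
  max(0, 1 + 0.12·d) and latencies shift by −3·d ms, so peaks are
  larger and earlier at higher SNR. The amplitude floor at 0 exists
  because a negative-gain kernel is physiologically meaningless.
* **Topography.** A Gaussian spatial gain bump (σ = 0.4 head radii,
  baseline 0.15, max 1) centred on the centroid of C3/CP3/CPz on an
  approximate 2-D 32-channel 10–20 layout. No volume conduction.
* **EEG.** channel = gain · topography · (envelope ⊛ kernel) +
  noise_sd · 1/f noise, independent per channel. The convolution uses
  exactly the design-matrix boundary convention, so noiseless data are
  reproduced exactly by the model — the basis of the round-trip tests.
  SNR dependence lives on the kernel, not on the stimulus: the clean
  envelope is the regressor at every condition.
* **Noise level.** noise_sd defaults to 13 a.u., which puts the
  stimulus-driven signal ≈10 dB *below* the background in the 1–10 Hz
  band at the best electrode — the typical in-band SNR of cortical
  evoked responses. White noise is available by flag for oracle tests.
* **Behavior.** Subjects' SRT_50 ~ Normal(−7.0, 0.9) dB. Word scores at
  ΔSNR = d are Binomial(100, f(d))/100 with the logistic psychometric
  function f(d) = 1/(1 + exp(−d/s)), s = 1.462 dB — the slope that
  reproduces the matrix-test anchor rates (≈94/80/59/41/20/6 % on the
  ±0.5, ±2, ±4 dB grid). 20 sentences × 5 words per condition.
* **Individual variability.** A log-normal per-subject response gain
  (sd 0.1) spreads RMS_sum levels moderately across subjects, consistent
  with response amplitudes being roughly comparable across listeners.
* **Seeding.** One master seed; every subject × condition × channel
  stream derives its child seed deterministically (SeedSequence with
  counter offsets), so a cohort regenerates byte-identically.

What the generator does **not** emulate: phoneme-level acoustics, volume
conduction, ocular/muscle artifacts, non-stationary attention, or any
nonlinearity between envelope and cortex. Passing tests therefore show
the *pipeline* is correct and well-calibrated under its own model
assumptions; they do not certify performance on real recordings.

## Features

Per TRF (subject × condition × electrode):

* **N1**: first local minimum with negative value in 75–175 ms, found by
  the sign change of the discrete first derivative scanned in ascending
  latency; **P2**: first local maximum with positive value in
  175–300 ms. Amplitude is reported as |value|. If no peak of the right
  polarity exists, amplitude = 0 and latency = the window maximum.
  Plateaus count at their first sample; no interpolation is performed —
  everything stays on the 8.33 ms lag grid.
* **Windowed RMS**: root mean square over lags in a per-electrode window
  [lower, upper] ms, endpoints inclusive (window edges are lag-grid
  multiples). The window is optimized by exhaustive grid search, lower
  in 0–100 ms and upper in 108–200 ms at lag resolution (156
  candidates), maximizing the mean over subjects of the per-subject
  Spearman ρ between ΔSNR and the RMS. Ties break to the narrowest
  window, then the smallest lower edge. The mean-of-per-subject-ρ
  criterion (not pooled ranks) matches how the monotonicity statistic is
  defined; a pooled variant would weight subjects by their feature
  spread.
* **RMS_sum**: sum of the windowed RMS over C3, CP3 and CPz (config
  default; a data-driven subset is deliberately *not* re-derived per
  dataset, keeping the composite comparable across cohorts).

## Statistics

Per electrode and feature: per-subject Spearman ρ against ΔSNR (midrank
ties; a constant feature vector yields ρ = 0 with a warning so the
electrode map stays total), averaged over all subjects; a Kruskal–Wallis
test across the six conditions (tie-corrected, df = 5; all-identical
observations give H = 0, p = 1); and, when it rejects at α = 0.05,
Dunn z tests on midranks with tie correction, Bonferroni-multiplied by
the 15 condition pairs and clipped at 1. Two-sided p-values throughout.

## SRT_50 prediction

Behavioral scores pooled over subjects are fitted with the logistic
psychometric function (nonlinear least squares; deterministic
initialization: SRT at the score nearest 50%, slope 1.5 dB, with a small
multi-start ladder). The EEG feature is linked to intelligibility by the
one-parameter exponential

    Intelligibility = 100 · (1 − e^(−b·RMS_sum)) %,

fitted by least squares; the 95% CI for b uses the linearized (Jacobian)
standard error with normal quantiles. The threshold RMS_50 = ln 2 / b is
the RMS_sum at 50% intelligibility.

Prediction is leave-one-out: b is fitted without the evaluated subject,
and that subject's conditions are scanned in ascending ΔSNR; the first
condition with RMS_sum ≥ RMS_50 (≥ makes the boundary deterministic) is
the predicted SRT_50. The crossing stays on the discrete condition grid —
no interpolation — and since the grid is defined relative to the
behavioral SRT_50, the prediction error in dB is the predicted ΔSNR
itself (sign convention: predicted − behavioral). Subjects that never
cross are flagged rather than extrapolated.

## Numerical choices and degenerate inputs

* Ridge systems are solved with a direct solver; a condition number
  above 10¹² (e.g. λ = 0 with a degenerate envelope) raises rather than
  returning garbage.
* Pearson/Spearman on constant series raise (prediction correlation) or
  fall back to 0 with a warning (electrode maps), respectively.
* The filter refuses signals shorter than its length; resampling refuses
  upsampling (the pipeline only ever moves down to 120 Hz).
* Window search skips candidate windows whose feature is constant across
  all subjects and conditions, and errors if every candidate is.

## Problem sizes

Default runs use the full study geometry: 18 subjects × 6 conditions ×
32 channels (3,456 TRFs) with 540 s of stimulus per condition. The full
pipeline completes in about a minute on one core; unit tests use smaller
cohorts (2–8 subjects, 20–60 s stimuli, ≤ 4 channels) chosen so every
statistical assertion still has the power it needs.

## Known limitations

* The λ convention follows the raw normal equations; toolboxes that
  rescale the penalty by the mean eigenvalue of SᵀS will produce
  differently scaled coefficients (identical up to that reparametrization).
* The exponential intelligibility link is deliberately simple; it
  saturates by construction and underfits near 100% (visible as a
  ~20% fit RMSE on cohorts whose scores pile up at the extremes).
* Real-mode import (EDF/BrainVision/WAV) is functional but artifact
  removal beyond the hook, re-referencing and bad-channel handling are
  out of scope.
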