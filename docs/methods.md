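# Methods

This note documents the models, conventions and numerical choices behind
hypnocycle, what the synthetic generators do and do not emulate, and the
limits of what the test suite demonstrates.

## Hypnodensity representation

A hypnodensity series holds one 5-vector of stage probabilities per time
step on a constant grid.  Conventions fixed across the package:

* **Canonical stage order** Wake, N1, N2, N3, REM (indices 0–4), used in
  every array, file and plot.  The order is the common AASM presentation
  order; fixing it makes files and correlation values comparable.
* **Window-center assignment.**  Sliding-window quantities are assigned to
  the center of their window; only windows fully inside the record are
  emitted (no padding), so series edges carry no partially-informed frames.
  Defaults: 30-s window, 5-s step.
* **Simplex contract.**  Rows must be non-negative and sum to 1 within
  1e-6; `validate_series` reports the first violated invariant.
* **Argmax collapse.**  `hypnodensity_to_hypnogram` breaks exact ties
  toward the lower stage index.  Ties are a measure-zero event for softmax
  outputs; the rule exists to make the collapse deterministic.
* **Artifact gaps.**  Artifact-marked epochs are excluded.  The default
  policy concatenates the remaining record onto a contiguous time base
  (with a logged warning) because the lagged correlations assume a
  contiguous frame index; a `split` policy returning per-segment series
  with original timestamps is available when wall-clock timing matters.
  Concatenation slightly distorts lags across gap boundaries — with few,
  short artifacts the effect on a full-night estimate is negligible, but
  heavily fragmented recordings should use `split` and per-segment
  analysis.
* **Dataset splitting** rounds the train share half-down, so 68 recordings
  at 80 % give the conventional 54/14 partition.

## Vectorial lagged correlation

For series x, y of equal length T and step, with per-stage means x̄, ȳ:

    r_xy(τ) = [ (1/(T−τ)) Σ_{t=1..T−τ} (x_t − x̄)·(y_{t+τ} − ȳ) ]
              / sqrt[ (1/T) Σ ‖x_t − x̄‖² · (1/T) Σ ‖y_t − ȳ‖² ]

with r_xx the y = x case.  Implementation notes:

* The numerator/denominator normalization mismatch (1/(T−τ) vs 1/T) is
  kept **verbatim**: |r| may slightly exceed 1 at large lags, and values
  are never clamped.  Oracle tests pin the implementation to a naive
  double-loop transcription of the sums at 1e-12.
* The lag grid equals the series step; negative lags are served by
  argument swapping (r_xy(−τ) = r_yx(τ)), since the sum is written for
  τ ≥ 0.  `max_lag` defaults to half the record.
* Sums are evaluated via FFT (the 5 per-stage cross-correlations are
  accumulated in the spectral domain); r(0) is set from the directly
  computed denominator so the lag-zero value is exactly 1 for the
  auto-correlation.
* A constant series has zero variance and no defined correlation; this
  raises a typed `DegenerateInputError` instead of propagating NaN into
  peak detection.
* Correlations are invariant to a consistent permutation of stage labels
  (the deviation dot product is permutation-invariant); this is property-
  tested.

## Period estimation by local side-maxima

`detect_local_maxima` smooths the curve with a centered moving average
(default width 10 min), finds interior maxima with prominence ≥ 0.1 at
lags ≥ 30 min (excluding the trivial global maximum at τ = 0), then
refines each candidate to the local maximum of the *unsmoothed* curve
within half a smoothing window, reporting lags on the original grid.  The
first admissible maximum is the period estimate; "no cycle detected" is a
status, not an exception.

Parameter rationale (all exposed in the API and CLI):

* **Smoothing 10 min** suppresses frame-level probability noise without
  displacing cycle-scale maxima; the raw-grid refinement removes the
  residual bias smoothing can introduce on asymmetric peaks.
* **Minimum lag 30 min** excludes the zero-lag peak and its shoulder;
  plausible human cycle periods lie well above it.
* **Prominence 0.1.**  On full-night series, genuine cycle repeats have
  prominences near 0.9, while a stage recurring twice *within* one cycle
  (N2 before and after N3 in the standard progression) produces faint
  side-lobes with prominences below ~0.05.  The default separates the two
  regimes by an order of magnitude; it is a calibration on the package's
  synthetic nights, not an empirical constant of real sleep.
* **Windowed variant.**  `windowed_period_track` repeats the analysis on
  consecutive record parts for non-stationary periods.  Parts shorter than
  about four expected periods give unstable estimates (a warning is
  issued); each part needs `max_lag` beyond the longest period of
  interest.

## Synthetic night model

`CyclicSleepModel` generates a night as a succession of ultradian cycles
realizing the template N1 → N2 → N3 → N2 → REM with dwell fractions
0.10/0.40/0.25/0.10/0.15 — a plausible textbook-style progression; the
fractions are package defaults, not fitted values, and the correlation
mathematics does not depend on them.

* **Stable ultradian clock.**  `dwell_jitter` (log-normal σ, default
  0.05) perturbs how stages share each cycle, after which dwells are
  rescaled so every cycle occupies exactly `round(period / 30 s)` epochs.
  The generator therefore models within-cycle variability around a fixed
  cycle clock.  This is a deliberate design: the generator's contract is
  that the nominal period is recoverable from the auto-correlation to
  within one lag step in ≥ 90 % of nights, which bounds how much cycle-
  length variability the model may contain.  At σ ≈ 0.1 the stage-boundary
  scatter already displaces the empirical correlation maximum by one 30-s
  epoch in over 10 % of nights (the peak top becomes flat and near-tied at
  Δr ≈ 0.001), so the default sits at 0.05.
* **Brief awakenings** are inserted as 1-epoch Wake events at a Poisson
  rate (default 1/h), a crude stand-in for arousals.  Raising the rate
  degrades the cycle peak — a severity knob for fragmented-sleep
  scenarios — but no arousal microstructure is modeled.
* **Softmax noise.**  Each frame draws a Dirichlet vector with parameters
  `concentration × target`, where the target is the true stage's
  confusion-kernel row (default: 0.85 self-mass, remainder mostly on
  adjacent stages such as N2↔N3) times an optional per-channel stage bias,
  renormalized.  Rows therefore lie exactly on the simplex, and at the
  default concentration (40) the frame argmax matches the true stage in
  well over 90 % of frames.  Channel biases emulate electrode-position
  effects (a central channel slightly over-reporting Wake, an occipital
  one over-reporting N3).
* **Not modeled:** first-cycle N3 dominance and REM lengthening across the
  night, stage-transition asymmetries, real inter-rater uncertainty
  structure, artifacts, any EEG microstructure.  Passing tests demonstrate
  the correctness and calibration of the *statistics* on cyclically
  structured simplex noise — not performance on clinical recordings.

The toy EEG generator assigns each stage a standard spectral signature
(alpha ≈ 10 Hz for Wake, slow high-amplitude delta for N3, burst-modulated
spindle-band activity for N2, theta-range activity for N1/REM) over
broadband noise, amplitude-normalized per epoch.  It exists to give the
classifier a learnable, physiologically flavoured task; it is not a
simulation of EEG.

## GDV

The GDV of a labeled point cloud: z-score each dimension over all points,
rescale by 0.5, compute the mean intra-class and mean inter-class
Euclidean distances, and return their difference scaled by D^(−1/2).
Under this convention identical-distribution classes score ≈ 0 and tight
clusters separated in every dimension approach −1.  The 0.5 rescaling is
what makes the perfect-separation limit land at −1; it is exposed as a
parameter.  Zero-variance dimensions carry no geometry after z-scoring and
are dropped with a logged warning (an all-constant cloud is degenerate).
Note that two clusters separated along a *single* dimension of many
plateau well above −1 even at large separation — the index rewards
separation relative to the full embedding geometry.

## MDS and figures

Projections use metric MDS (SMACOF, scikit-learn) on Euclidean distances
with a caller-supplied seed, fixed by default, because SMACOF is
initialization-sensitive; the raw stress is reported and stamped on
plots together with the caveat that absolute MDS coordinates only scale
relative distances.  Stage colors are fixed (Wake gold, N1–N3 light→dark
blue, REM red) for cross-figure consistency and are configurable.  All
plot functions are pure: they write the named file and return its path.

## Classifier

The classifier module realizes the canonical conv + recurrent sleep-scoring
layout: 1-D convolution/max-pooling blocks over a z-scored 30-s window,
bidirectional LSTM, dense softmax over the five stages.  The full-scale
layer census is 11 conv / 9 pool / 2 biLSTM; `scale_factor` shrinks depth
and width for desk-scale runs, where the claims are property-based
(learning well above chance on the synthetic EEG; separability improving
toward the softmax layer), never performance-based.  Layers and backprop
are implemented in plain numpy and verified against finite differences;
training uses Adam on cross-entropy.  Kernel sizes, widths and the
optimizer configuration are package defaults, documented in the code.
Recurrent state is confined to each 30-s window (the feature sequence the
conv stack produces); state is never carried across datasets.  No
pretrained weights ship, and nothing here is a claim about real-EEG
scoring accuracy.

## Problem sizes used in tests and the acceptance script

Synthetic nights are 8 h at 5-s resolution (5760 frames); period-recovery
rates use 50 seeded nights per condition; GDV calibration uses 500 points
per class in 10 dimensions over 20 seeds; classifier properties train a
scale-0.25 instance on ~400 windows for 10 epochs over 3 seeds.  These
sizes give stable statistics for the stated thresholds while keeping a
full run in the order of a minute.

## Known limitations

* The generator's fixed cycle clock means the package's recovery rates do
  not speak to nights whose cycle length drifts; the windowed tracker is
  the intended tool there, demonstrated on piecewise-constant synthetic
  periods.
* Peak prominence/smoothing defaults are calibrated on the synthetic
  regime; real hypnodensities with heavy artifacts or fragmented sleep may
  need different settings (all are exposed).
* No statistical significance is attached to correlation maxima, and no
  spectral (Fourier/Lomb–Scargle) period estimation is provided.
* EDF/real-PSG ingestion is out of scope; inputs are the documented text
  formats or in-memory arrays.
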