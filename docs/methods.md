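# Methods

This note documents the generative model, the signal-processing and
evaluation choices, and what the synthetic experiments do and do not
establish.

## Synthetic session model

Each participant's session is a multichannel time series at fs = 5.8 Hz
(fixed exactly; acquisition hardware of this class reports "approximately"
this rate). The protocol is three groups of (task A, 120 s rest, task B,
120 s rest); task-block length is participant-paced in the real experiment
and is therefore a free parameter, default 300 s. Samples per block are
floor(duration × fs), so labels tile the sample axis exactly.

A long channel at position p (side s ∈ {lateral, medial}, chromophore
c ∈ {HbO, HbR}) is generated as

    y_p,c(t) = r_s,c(t) + g_s · κ_c · u_s(t) + ε(t)

with:

* **Sustained task response** r: for each task, the canonical double-gamma
  HRF (peak 6 s, undershoot 16 s, undershoot ratio 1/6) convolved with the
  task boxcar. The kernel is normalised to unit sum, so an "effect
  amplitude" a (µM) is the plateau of the sustained response during that
  task's blocks. Default HbO amplitudes: medial 1.0 µM for visualization /
  0.3 µM for workload, mirrored laterally — medial (DMN-proxy) positions
  respond preferentially to the internally directed task, lateral
  (DLPFC-proxy) positions to the workload task. κ_HbR = −0.3 (inverted,
  smaller HbR response), configurable.
* **Task-modulated in-band oscillation**, part of r: unit-variance
  band-limited (0.1–0.4 Hz) Gaussian noise per side whose instantaneous
  amplitude is `task_oscillation_gain` (default 0.5) times the positive
  part of the sustained-response envelope. Rationale: the analysis
  bandpass (below) is ≥ 20 dB down at 0.01 Hz, and a sustained block
  response concentrates essentially all of its energy below ~0.08 Hz —
  after filtering, mid-block windows of a pure boxcar⊗HRF response carry
  no class information at all. Physiologically, sustained task engagement
  modulates the amplitude of low-frequency cortical vasomotor activity;
  this modulation is the component of a block design that windowed
  features of bandpassed fNIRS actually measure. Without this term no
  classifier can beat chance on mid-block windows, with it the window
  statistics (max, std) become task-discriminative.
* **Superficial physiology** u_s: one process per probe side — cardiac
  (0.4 µM at 1.1 Hz), respiration (0.2 µM at 0.25 Hz), Mayer waves
  (0.3 µM at 0.1 Hz) and slow drift (0.3 µM at 0.01 Hz), each a sinusoid
  with a participant-random phase. Synthesis is band-limited at the
  sampled rate; at fs = 5.8 Hz the Nyquist frequency (2.9 Hz) is above the
  cardiac line, so no component aliases. The short channel of side s
  observes u_s plus white noise and nothing else — the idealisation that
  makes RLS recovery exactly testable (the fitted slope must converge to
  the coupling gain g_s).
* **Coupling and noise**: g_s defaults to 0.5; white noise sd 0.1 µM.
  Participant variability multiplies effect amplitudes, gains and noise
  sds by log-normal factors with σ = 0.3, drawn once per participant.
  Per-participant seeds come from a counter-based stream
  (`SeedSequence(global_seed, spawn_key=(i,))`), so enlarging a cohort
  never perturbs existing participants.

Raw-intensity mode forward-models ΔHb to 690/830 nm intensities by
inverting the MBLL (ΔOD = d·DPF·E·Δc, I = I₀·10^(−ΔOD)) around a unit
baseline intensity. The generating I₀ is stored in channel metadata: an
I₀ estimated from a baseline window recovers ΔHb only up to a constant
per-channel offset (the log of the window-mean intensity), so the exact
round trip — and its 1e-6 µM test — requires the true baseline. Both
baseline conventions are supported by `MbllParams`.

What the generator does **not** emulate: motion artifacts, optode-coupling
drift, photon-transport geometry, phase (frequency-domain) measurements,
cross-side superficial correlation, and any systematic overlap between the
two tasks' neural signatures. Passing tests therefore show that the
pipeline recovers the signal its model assumes — they do not certify
performance on real recordings, where the paper-scale difficulty
(cross-participant heterogeneity, weak in-band signal) dominates.

## Conversion and filtering

Extinction coefficients are the Gratzer/Prahl values at 690/830 nm
(base-10, cm⁻¹·mM⁻¹): ε(690) = (0.276, 2.052), ε(830) = (0.974, 0.693)
for (HbO, HbR). DPF = 6.0 at both wavelengths (common adult-forehead
value); both are configurable, and the forward model uses the same table,
so round-trip validity does not depend on the specific values.

The hemodynamic bandpass is a 3rd-order Butterworth, 0.1–0.4 Hz. The
offline path uses zero-phase forward-backward filtering (no group delay);
the real-time path uses a causal single pass, because a live system cannot
filter backwards. Pipelines are trained and replayed with the same mode so
the frozen coefficients see matched inputs.

## Short-channel RLS

One filter per (side × chromophore), regressor x_t = [short_t, 1]
(intercept included), targets the side's three long channels, which share
the inverse-correlation matrix P. Defaults: forgetting λ = 0.999,
initialisation P₀ = δI with δ = 100 — with this initialisation the implied
ridge penalty is |w|²/δ, so large δ means weak regularisation and λ = 1
reproduces batch OLS (verified to 1e-4 relative). Filters are fitted on
the concatenated task trials of the training split, rest excluded
(configurable), and applied frozen everywhere else. A zero short channel
leaves slope coefficients exactly at 0; the intercept then learns the
target mean, so "removal" only de-means.

## Features, scaling, selection

Windows are non-overlapping (stride = window length) and never straddle a
block boundary; partial trailing windows are dropped; rest windows are
excluded (the classifier is binary A-vs-B). Statistics per channel: max,
mean, unbiased sample sd, Fisher skewness without bias correction (defined
0 for zero variance) and OLS slope against time in seconds (fs-invariant).
The online pipeline uses max+mean over 12 long ΔHb channels (24 features)
with standardisation and K = 10 F-test selection (ties broken toward the
lower feature index); offline analyses use all five statistics and no
selection. Scaling is per feature over training windows; applying frozen
parameters twice is deliberately not idempotent (documented behaviour of
frozen standardisation).

## Classifiers

scikit-learn estimators behind a uniform contract; grids are fixed:
SVM C ∈ {0.1, 1, 10} (linear kernel, squared hinge, ≤ 1000 iterations —
the capped iteration count can stop short of full convergence by design),
KNN k ∈ {3, 5, 7, 9} (Euclidean, uniform weights), LDA (no grid), QDA
reg ∈ {0.1, 0.5, 1}, MLP with one hidden layer of 10 or 50 ReLU units
(adam, ≤ 5000 iterations, seeded), RF with {10, 50, 100, 200} Gini trees
(seeded, unlimited depth). The real-time default is the linear SVM with
C = 1. Class order is fixed: Visualization = 0, Workload = 1.

## Evaluation

Macro precision/recall/F1 with the 0/0 → 0 convention (degenerate folds
print 0.000 rather than NaN). The across-participant summary is the mean
and *population* (n-normalised) standard deviation of per-participant
macro F1. Display rounding is half-up at 3 decimals.

Online replay walks the held-out third group in contiguous 100-frame
steps (17.24 s; the protocol's nominal "every 20 s" is treated as
approximate), applying the frozen RLS/scaler/selector/model per window —
floor(block samples / stride) predictions per task block, bitwise
deterministic across replays.

LOO-CV holds out one participant per fold. RLS coefficients and scaler
are fitted on the concatenated training cohort and applied frozen to the
held-out participant; hyperparameters are chosen by grouped inner LOO over
the training participants (best mean inner macro F1, ties toward the
smallest value). The scaler is fitted once per outer fold rather than
refitted inside each inner fold: inner validation rows belong to the
training cohort, so no test-participant information is involved. Both
POOLED (confusions summed over folds) and PER_FOLD_MEAN aggregations are
reported; they legitimately differ when folds have unequal window counts.
The leakage guard is structural: a hard `LeakageError` if the held-out
participant's windows ever appear in a fitting table.

The label-permutation null shuffles A/B identities across a session's
task blocks after generation, decoupling labels from hemodynamics while
preserving block structure — the pipeline must score ≈ 0.5 there. Because
each session has only six task blocks, a single permutation draw can
retain substantial label overlap by chance (per-participant overlap sd
≈ 0.22); the null score is therefore averaged over three permutation
draws, which brings its sampling sd below 0.05.

## Problem sizes

Integration tests and the acceptance script use 8 participants with 180 s
task blocks (the full three-group protocol otherwise) and the RF/SVM
families at 100-frame windows — a cohort size matching the study design
and a block length chosen to keep a full LOO-CV sweep comfortably
interactive; all unit-level oracles run on much smaller series. The full
window sweep {50…300} × six families × three source subsets is supported
by the same `loocv` call and scales linearly in cells.

## Known limitations

* The RLS recursion is a per-sample Python loop; cohort-scale fitting is
  O(n_samples) with small constants but not vectorised.
* SNIRF support is a minimal reader/writer (HDF5 layout, measurement list,
  stim and aux groups) sufficient for round-tripping this package's
  sessions, not a validator of third-party files.
* The synthetic strong-effect regime is deliberately well-separated;
  scores near 1.0 on it are a power check of the pipeline, not a
  performance claim about real prefrontal recordings.
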