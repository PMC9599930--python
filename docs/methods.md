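# Methods

This note records the models implemented in `vmdforest`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic data can and cannot show.

## Segmentation and labeling

Recordings are cut into contiguous, non-overlapping 4-s epochs.  Each
epoch holds exactly `floor(epoch_len_s * fs)` samples so non-integer
products (4 s at 173.6 Hz → 694.4) give a fixed length (694); the trailing
remainder shorter than one epoch is dropped.  Times are 0-based seconds
and intervals half-open `[start, end)`.  An epoch is labeled seizure when
its window overlaps an annotated interval by any positive amount — the
most sensitivity-preserving ground truth; the minimum overlap is
configurable for stricter labeling.

## Variational mode decomposition

The signal is decomposed into K band-limited modes by minimizing the
summed bandwidth of the analytic, baseband-shifted modes under a
reconstruction constraint, solved with ADMM entirely in the frequency
domain: a Wiener-filter update per mode spectrum,
`u_k(ω) ← (f(ω) − Σ_{i≠k} u_i(ω) + λ(ω)/2) / (1 + 2α(ω − ω_k)²)`, and a
spectral-centroid update per center frequency.

Parameters (all in `VMDConfig`):

- `K = 5` modes.  The over-decomposition diagnostic
  (`center_frequency_scan`) flags mode counts whose solver-order center
  frequencies rise and then fall.
- `alpha = 2000` — bandwidth penalty (dimensionless).  Standard practice
  for EEG-scale signals; larger values narrow the modes.
- `tau = 0` — dual-ascent step of the multiplier λ.  The default disables
  exact reconstruction enforcement, which is the robust choice for noisy
  EEG: enforcing `Σu_k = f` exactly would push broadband noise into the
  modes.  For clean band-limited signals (the reconstruction oracles in
  the test suite) the multiplier is enabled (`tau = 0.1`), which brings
  the two-tone reconstruction residual from ~7% (pure edge ringing, see
  below) to ≤ 2.5% without moving the center frequencies.
- `tol = 1e-7` summed relative spectral change, `max_iter = 500`.
- Center frequencies are initialized uniformly over `[0, 0.5)`
  cycles/sample, making the solver fully deterministic.

Boundary handling: the epoch is mirror-extended (even reflection) by half
its length on each side before the transform and the center section is
retained.  The even extension is value-continuous but has a derivative
kink exactly at the retained-section edges; for signals with maximal
slope at the epoch boundary the narrowband filters ring there, leaving a
few percent of edge-localized residual at `tau = 0` (interior residual is
an order of magnitude smaller; the property suite checks both).  An
antisymmetric (derivative-continuous) extension was evaluated and
rejected: it injects a step-like trend that captures the lowest mode.

Modes are returned sorted by ascending center frequency (the low-to-high
VMF1…VMFK convention).  Mode screening keeps modes whose Pearson
correlation with the original signal is strictly greater than 0.3;
"not greater than" is the rejection condition.  The residual is defined
as input minus mode sum, so modes + residual reconstruct the input
exactly by construction.

## LECM features

The selected modes of all channels form the epoch's time–frequency
matrix in channel-major column order.  Its covariance uses removed column
means, the (n−1) divisor, and a tiny ridge `1e-10 · trace(C)/d` on the
diagonal so the matrix is strictly SPD even with collinear columns and
the log map is always defined.  The matrix logarithm is computed from the
symmetric eigendecomposition, `log C = U·Diag(log λ_i)·Uᵀ`; eigenvalue
ties are harmless because only `U f(Λ) Uᵀ` is used.  Half-vectorization
keeps the diagonal and above, read column by column
(C11, C12, C22, C13, …, Cdd), with no √2 weighting of off-diagonal
entries — the feature is the raw upper triangle.  One channel with three
retained modes gives 6 features; a three-channel focal montage gives 45.

## Deep forest

Multigrain scanning slides windows of length 5 and 3 (stride 1) over the
feature vector; each window is classified by one random forest
(√d features per split) and one completely-random forest (one random
feature, random threshold, grown to purity — `ExtraTreesClassifier` with
`max_features=1`), and all window class probabilities are concatenated.
Scanning forests use 120 trees, the same count as cascade forests.

Each cascade level holds two random and two completely-random forests of
120 trees.  A level's input is the scanned vector concatenated with the
previous level's class vectors; during training those class vectors are
out-of-fold predictions from a stratified 3-fold split, so later levels
never see resubstitution probabilities.  Validation accuracy per level is
the accuracy of the averaged out-of-fold class vectors; growth stops when
it fails to improve by more than 1e-4 for one level (patience 1) or at 20
levels, and the model keeps the best-accuracy depth.  The unscanned
feature vector is not re-appended at cascade levels.  Prediction averages
the final level's four class vectors; class order is
[nonseizure, seizure].  All randomness derives from one integer seed;
equal seeds give bit-identical predictions.

When the tuned mode selection yields a feature vector shorter than a
configured scanning window (e.g. two kept modes → 3 features), the
pipeline drops the oversized windows rather than failing, falling back to
a single full-width window if necessary.

## Postprocessing

The classifier margin `P(seizure) − P(nonseizure)` per epoch is smoothed
with a linear moving-average filter of half-width M (window 2M+1, capped
at 35 epochs).  Boundary points average only the in-range samples
(truncated window), so constants are preserved at the edges and no
phantom zeros enter.  Decisions use a strict `>` comparison with the
threshold — ties go to nonseizure, the conservative class.  The collar
extends each detected run by `collar_epochs` on both sides (extensions
merge); its default is M, compensating the onset/offset blurring the
smoothing introduces, and can be overridden per patient.

Window and threshold are tuned by exhaustive grid search on the training
series: odd windows 1…35 crossed with margin quantiles plus a fixed
−0.9…0.9 grid, maximizing the epoch-level G-mean (robust to the heavy
class imbalance of long-term EEG); ties prefer the smaller window, then
the lower threshold, so tuning is deterministic.

## Evaluation

Epoch-based: sensitivity, specificity, accuracy as percentages, and
G-mean as the geometric mean √(sensitivity × specificity) — the geometric
mean, not the raw product, is what makes the metric comparable to its
factors.  Event-based: maximal runs of positive epochs are events; a
reference event counts as detected when at least one detected event
overlaps it by any positive duration (each reference counted once), and a
detected event overlapping no reference is one false positive.  The false
detection rate divides false positives by total evaluated hours (seizure
time is not excluded).  Cross-patient summaries pool events for the
event sensitivity but average the per-patient hourly rates unweighted.

## Synthetic data

`generate_record` emulates a focal intracranial montage: 1/f^β background
(β = 1) from spectrally shaped seeded white noise at a 50 µV RMS scale,
plus, during each scripted seizure, a harmonic-rich rhythm (3–5 Hz
fundamental with 3 harmonics at 1/h amplitude decay, random phases)
ramped linearly over 2 s at onset and offset.  `amplitude_ratio` is the
ictal-to-interictal amplitude ratio: the added rhythm is scaled to
`(ratio − 1) ×` background RMS, so ratio 1 adds nothing — a labeled
interval with no signature, used for the chance-level control.  A white
sensor-noise floor sits 15 dB below the background by default.  One seed
drives all draws.  Dataset assembly balances the training epochs by
subsampling the majority class (mirroring training on a seizure event
plus an equal amount of nonseizure data) and leaves the test series
imbalanced.

What this does not emulate: spatial correlation between channels,
artifacts (EMG, movement, electrode pops), non-stationary background
drift, and the morphological variety of real seizures.  Passing the
synthetic end-to-end checks therefore demonstrates that the pipeline is
internally consistent and can recover a known rhythmic signature at a
realistic amplitude ratio — not that clinical-grade accuracy transfers to
real recordings.

## Problem sizes

The bundled end-to-end runs use single-channel 600-s records (150 epochs)
with one 60-s seizure for the recovery checks, 300-s records for the
chance-level control, and 200-sample blob fixtures for the classifier
checks.  These sizes are the package's own choice of a small but
non-trivial regime: one seizure per record, a 10% seizure prevalence in
test data, and enough background epochs for the tuning grid to be
meaningful.

## Known limitations

- VMD edge ringing at `tau = 0` (above) is intrinsic to the mirror
  boundary; detection is unaffected because features are covariances over
  whole epochs, but per-sample mode waveforms near epoch edges should not
  be over-interpreted.
- The collar's adaptation rule is the M-linked default, a documented
  stand-in; no claim is made that it matches any particular clinical
  collar scheme.
- `tune_params` is O(windows × thresholds × n); for very long training
  series the quantile grid dominates — acceptable at clinical epoch
  counts (an hour is 900 epochs).
- The cascade refits scanning forests per training call; models are
  record-specific by design (per-patient training), and no warm-start API
  is provided.
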