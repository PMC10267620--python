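# Methods

`timedecode` implements a complete time-resolved multivariate decoding
analysis for epoched EEG from a 2 × 2 working-memory design — perceptual
*availability* (stimulus visible 150 ms vs 1850 ms of a 2 s delay) crossed
with feature *relevance* (the decoded spatial frequency is the task feature
or not) — together with the nonparametric inference used to compare
decoding time courses, a gaze-decoding confound control, and a synthetic
generator that makes every stage testable without access to recorded data.

## Preprocessing

Input is artifact-cleaned epoched data (trials × channels × timepoints,
µV, epochs −1500…3500 ms around sample onset). The conditioning chain is

1. channel selection: 20 posterior channels (PO7, PO3, O1, Oz, POz, Iz,
   PO8, PO4, O2, P1–P10, Pz) — visual representations live posteriorly;
2. absolute baseline correction over [−500, 0) ms;
3. zero-phase (forward–backward) Butterworth lowpass, cutoff 8 Hz.
   The filter order is not dictated by the protocol; the default is 5,
   configurable. The two-pass magnitude is `1/(1 + (f/8)^10)`, verified
   against the analytic response in the suite;
4. downsampling to 50 Hz by decimation (keep every k-th sample). With the
   8 Hz lowpass in place decimation is alias-free; polyphase resampling
   would only smear the time axis.

All windows are closed-open `[start, end)` in milliseconds, so resampling
arithmetic is exact. Every step is per-trial, hence preprocessing commutes
bitwise with trial subsetting (a suite invariant). Re-referencing to the
T7/T8 average, a 0.01–80 Hz bandpass and a 50 Hz notch are available as
optional operations for full-montage real recordings; synthetic data are
generated reference-free at the analysis montage and skip them.

## Decoding model

Per participant and condition, correct-response trials are binned into 4
equal-count spatial-frequency classes (quantile binning *per participant
and condition*: the protocol specifies "classes of equal size", and fixed
frequency edges belong to the behavioural staircase, not the decoder),
class counts are equalised by seeded subsampling, and trials are randomly
partitioned within class into 3 folds whose per-class averages form
pseudo-trial exemplars. At every training timepoint a one-versus-all
linear SVM per class (C = 1) is fitted on the (n_folds − 1) × n_classes
training exemplars and applied to the held-out fold's exemplars at every
testing timepoint, giving a signed distance to the decision boundary per
(test exemplar, classifier, train time, test time). The fold rotation runs
3 times and the whole partition is redrawn for `n_shuffles` repetitions
(protocol value 10).

Scores are z-scored per participant × shuffle repetition × classifier
across all folds, test exemplars and timepoints (the normalisation scope is
configurable; this default is the widest scope that never mixes classifiers
or repetitions), multiplied by the true class label (+1 for the
classifier's own class, −1 otherwise) and averaged over classifiers. Chance
is 0 by construction; the diagonal (train = test) is the decoding time
series, the full matrix the temporal generalization matrix (TGM).

Two derived analyses reuse the same machinery:

* **early-window cross-condition training** pools both availability
  conditions (same relevance), builds folds stratified by class ×
  availability — stratification guarantees every fold contains test
  exemplars of both conditions, which plain class-stratified folding does
  not — trains only at timepoints inside [87, 150) ms (at 50 Hz: 100, 120,
  140 ms) and tests per condition at all timepoints, averaging over
  training timepoints (averaging over per-timepoint models was chosen over
  a single model on the concatenated window; both answer "do early sensory
  patterns generalize?", the average keeps the per-timepoint model
  identical to the main analysis);
* **binary condition decoding** relabels trials by condition membership
  (e.g. relevant vs irrelevant at long availability), equalises counts and
  runs the identical pipeline with 2 classes.

### The batched SVM solver

One analysis requires millions of independent tiny QPs (8 exemplars × 20
features, one per timepoint × class × fold × shuffle × participant ×
condition). `timedecode.svm` solves them simultaneously: dual coordinate
descent on the hinge-loss, L2-regularised, bias-augmented linear SVM — the
QP `LinearSVC(loss="hinge")` solves — vectorised across problems, with
deterministic coordinate order and an active set that retires converged
problems. Agreement with `sklearn.svm.LinearSVC` decision values (≤ 1e-6)
and with the closed-form maximum-margin boundary on separable toys is
asserted in the suite. Training sets whose exemplars are all identical are
flagged degenerate and score 0 (permutation loops must not abort on rare
degenerate resamples).

A scale caveat inherent to fixed-C SVMs: when feature variability is far
below the margin scale (≪ 1 in feature units), the optimum collapses to
the majority-class solution (w ≈ 0, b ≈ −1); after label-signing, that
common negative bias becomes a spurious *positive* score at uninformative
timepoints. EEG voltages (µV-scale noise) never enter this regime; gaze
does if measured in degrees. Gaze is therefore decoded in screen pixels,
the tracker's native unit (default 43 px/°, a 2560-px 27″ display at
58 cm).

## Cluster-based permutation inference

Group inference operates on participant-mean diagonal score series inside
the 0–2000 ms analysis window with per-timepoint one-sample t tests
(df = n − 1, zero-variance timepoints give t = 0) thresholded at the
two-sided α = 0.05 t quantile. Positive suprathreshold runs are clusters;
a cluster's mass is its summed t values.

* **Within-condition**: the observed statistic is the largest cluster
  mass. Null datasets multiply each evaluation's *entire* score series by
  an independent random sign — preserving temporal autocorrelation while
  destroying systematic above-chance evidence. The flip unit is one
  evaluation (shuffle × fold × test exemplar), the closest analogue of a
  trial once test items are fold averages; whole-participant flipping is
  available. Rejection: observed mass > 95 % null quantile; the reported
  p uses the add-one rule (never exactly 0).
* **Between-condition** (paired): the observed statistic is the veridical
  difference massₐ − mass_b, each mass from that condition's own cluster
  pipeline; permutations exchange both conditions' data for a seeded
  random ⌊n/2⌋ of participants, and the null is rejected when the observed
  difference exceeds the 95 % null quantile (one-sided, "A decodes
  more/longer than B"). A direction-agnostic absolute-difference mode
  exists behind a flag. With exactly half the participants swapped, both
  permuted mixtures have identical condition composition, so the null
  captures pure participant-recomposition variability.

Secondary observed clusters are reported descriptively but never tested —
only the largest cluster enters the decision. Isolated suprathreshold
timepoints are expected at rate α and should not be over-read.

## Synthetic data generator

The generator is the package's ground truth, not a model of the brain. Per
trial: EEG = envelope(t, condition) · class pattern + relevance term +
noise, where

* class patterns (4) and a relevance pattern are mutually orthogonal
  unit-norm topographies (QR of a seeded Gaussian matrix), one bank per
  dataset — class and condition information occupy independent spatial
  subspaces;
* the envelope is 0 pre-stimulus, then a Gaussian transient (default peak
  120 ms, SD 40 ms, amplitude 3 µV of pattern energy) plus a sustained box
  whose amplitude (4 µV) and duration depend on condition. Default
  durations 1200 / 650 / 400 / 400 ms for short-relevant / long-relevant /
  short-irrelevant / long-irrelevant emulate a profile in which relevance
  and brief availability prolong the sustained representation;
* the relevance pattern (same temporal shape, 2.5 µV) is added only in
  feature-relevant trials, making relevant vs irrelevant conditions
  linearly separable regardless of stimulus class;
* noise is AR(1) in time (φ = 0.9 at 100 Hz, ≈100 ms correlation time)
  with spatially mixed innovations (unit-row-norm mixing of strength 0.5),
  stationary SD 3 µV per channel;
* gaze is a 2-D random walk (total drift SD 0.5°) with an optional
  class-coupled step deflection (0.3° along four cardinal directions) from
  a configurable onset, off by default;
* spatial frequencies are drawn uniformly from the 48-point grid on
  [1, 4] cycles/°; the correct flag is Bernoulli(0.75) *independent of the
  EEG*, so correct-trial filtering is testable without a behavioural model.

Amplitudes are calibration choices, not measured quantities: they were
calibrated so that, at the design's sample size (24 participants, 128
trials/condition), per-condition decoding and the between-condition
duration contrast are adequately powered effects — matching the regime of
a study whose condition contrasts were highly significant — and they are
not tuned per test. The between-condition contrast is by far the most
demanding quantity: its permutation null reflects whole-cluster
mass jumps under participant recomposition, so its power rises steeply
with the sustained signal-to-noise ratio while the within-condition
offsets are stable from far lower amplitudes. Defaults generate directly at 100 Hz (the
post-preprocessing rate); srate is configurable.

What the generator does *not* emulate: 1/f spectra and oscillations,
artifacts (blinks, muscle), electrode drift, realistic forward-model
topographies, behavioural–neural coupling, saccadic eye-movement dynamics.
Passing tests therefore validate the *pipeline's statistical machinery*
(calibration, power, determinism, chance-centring) — not claims about any
real dataset.

## Built-in studies and problem sizes

`timedecode.studies` packages four end-to-end checks; sizes are desk-scale
choices (single CPU, minutes):

* **type-I calibration** — 200 signal-free score datasets (24 × 120
  evaluations, AR(1) score noise), 500-permutation within-condition tests:
  rejection rate ≈ α;
* **condition-profile recovery** — 20 runs of the full 24-participant
  design; per run, all four conditions are decoded (diagonal, 0–2000 ms, 2
  shuffle repetitions — decoding cost is linear in shuffles while group
  statistics are participant-driven) and tested at 500 permutations; the
  run succeeds if significant-decoding offsets order short-relevant >
  long-relevant > both irrelevant, and the between test separates short
  from long availability;
* **chance-level contract** — 50 label-shuffled decoding runs: grand-mean
  signed score ≈ 0;
* **gaze dissociation** — 20 runs (10 participants) with gaze–class
  coupling from 1400 ms: the largest significant gaze cluster must start
  at the onset (to one-sample resolution) while the EEG cluster ends
  before it.

`scripts/acceptance.py` recomputes all four from scratch under one seed.

## Numerical and degenerate-input conventions

* Sample standard deviations use ddof = 1 throughout; zero-variance scopes
  z-score to 0, zero-variance timepoints give t = 0.
* Equal-count binning breaks ties by stable original order; class sizes
  differ by at most one (earlier classes take the remainder).
* Fold assignment drops trials beyond the largest multiple of n_folds
  (seeded), never reuses a trial across folds.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical (data, config, seed)
  reproduce every stage bitwise, including CLI outputs (formats carry no
  timestamps).
* Monte-Carlo p-values use (1 + #{null ≥ observed}) / (n_perm + 1).

## Known limitations

* The score construction (z-scoring over a broad scope, ±1 signing with
  K − 2 net negative weight) reallocates any common classifier bias across
  the scope: strong signal windows induce a small opposite-signed ripple
  elsewhere in the same scope. It is inherent to the published score
  definition; interpret sustained *clusters*, not small local dips.
* The between-condition permutation test swaps whole participants
  (⌊n/2⌋ exactly); with very small groups the null support is coarse.
* Decimation assumes the lowpass has been applied; `resample` does not
  check it.
* The generator's orthonormal patterns make class geometry maximally
  benign; real sensor covariance will lower absolute scores (the package
  makes no claims about absolute decodability).
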