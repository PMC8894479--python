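# Methods

`eegsel` studies how well low vs. high arousal and low vs. high valence can
be decoded from multichannel EEG, and which small channel subsets suffice.
It implements the full protocol on DEAP-shaped data — 32 named 10–20
channels, 40 one-minute trials per subject at 128 Hz, continuous SAM ratings
in [1, 9] — and a seeded synthetic generator so every stage is testable
without the gated external dataset.

## Preprocessing protocol

Recordings are band-pass filtered 4–45 Hz, re-referenced to the common
average (CAR), and cut into non-overlapping segments of 2, 5, 10 or 60 s.
Ratings are binarized at 5: a rating < 5 is Low, otherwise High. Classes are
balanced per subject by dropping surplus trials of the majority class
(min(n_low, n_high) per class), so 19 low + 25 high trials yield 38 retained
trials, hence 228 ten-second or 1140 two-second instances. Instances are
split 50/25/25 into train/validation/test.

Design choices the protocol leaves open, fixed here:

- **Filter**: 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`), so the pass band is phase-neutral; only the band edges
  (4–45 Hz) are part of the protocol definition.
- **Resampling**: polyphase rational resampling with built-in anti-alias
  filtering (`resample_poly`); 512 Hz × 60 s → 7680 samples at 128 Hz.
- **Threshold tie**: a rating of exactly 5 is High ("< 5 is Low, otherwise
  High").
- **Balancing**: surplus trials are dropped by seeded uniform sampling; a
  deterministic first-k option exists for exact reproduction of a
  selection.
- **Split arithmetic**: per class, partition sizes come from
  largest-remainder quotas with the leftover rotated across classes, so a
  balanced 1140-instance set splits exactly 570/285/285.
- **Split grouping**: segment-level stratified splitting is the default
  (the conventional choice in this protocol family). Because sibling segments of one trial are
  strongly correlated (they share the trial's slow background activity),
  segment-level splits leak trial identity across partitions; a trial-level
  grouping mode assigns whole trials to partitions and is used wherever a
  claim about cross-trial generalization is being tested. Measured on
  synthetic data, uninformative channels score ≈ 0.62 under segment-level
  splits purely by trial fingerprinting, and chance (≈ 0.5) under
  trial-level splits.
- **k-fold**: 10-fold stratified CV, with k shrunk to the instance count
  for subjects with fewer than 10 instances.

## DWT features and classical baseline

Each channel of a segment is decomposed with a 4-level discrete wavelet
transform into five sub-bands (A4, D4…D1). Per sub-band, four scalars are
computed — log10 Teager energy (mean |x_i² − x_{i−1}x_{i+1}|), log10
instantaneous energy (mean x²), Higuchi fractal dimension (slope of
log-curve-length vs. log 1/k, kmax = 8), and Petrosian fractal dimension
(closed form in the number of sign changes of the first difference) — 20
features per channel. The wavelet family is Daubechies-4 with symmetric
extension; family and kmax are configurable and documented rather than
asserted as a replication of any particular prior choice. log arguments are
clamped at 1e-12 so silent sub-bands produce a finite sentinel instead of
−inf.

The baseline classifiers are SVM (kernels sigmoid/linear/rbf, C ∈
{0.1, 1, 10}), Gaussian naive Bayes, and kNN (1–9 neighbors), each behind a
standard-scaler, selected by cross-validated accuracy on the same folds
(non-nested selection; a nested scheme would cost k times more, and the
resulting optimism bias is listed under limitations). Accuracies are
summarized across
subjects by unweighted mean and sample standard deviation (ddof = 1).

## Compact CNN

The network is the compact EEGNet design: a temporal convolution whose
kernel spans half the sampling rate (64 samples at 128 Hz, acting as learned
band-pass filters), a depthwise spatial convolution across electrodes under
a max-norm-1 constraint, batch normalization, ELU, dropout and average
pooling (4); then a separable convolution (depthwise length 16 + pointwise),
a second BN/ELU/dropout/average-pooling (8) stage, and a dense softmax layer
with N = 2 units (max-norm 0.25). Widths default to F1 = 8 temporal filters,
depth multiplier D = 2, F2 = 16 pointwise filters, dropout 0.5.

The implementation is self-contained on NumPy: every layer has an explicit
forward and backward pass (the temporal convolutions run as FFT
convolutions), optimized by Adam (lr 1e-3, batch 16, cross-entropy), with
max-norm projection after every step. Gradients are verified against central
finite differences in the test suite to ~1e-8 relative error. All
stochasticity (initialization, batch order, dropout) flows from a single
seeded generator, so training is bit-reproducible. Inputs are standardized
per channel with training-set statistics. Training runs a fixed number of
epochs (default 200) and restores the weights of the epoch with the highest
validation accuracy (earliest epoch on ties); reporting the
best-validation checkpoint rather than the final epoch is the package's
convention, stated here because the two can differ.

A "tiny" profile (F1 = 4, F2 = 8, batch 32, ≤ 50 epochs) is the desk-scale
configuration used throughout the test suite and the synthetic experiments.

## NSGA-II channel selection

A chromosome is a binary mask, one gene per montage channel. Fitness is
(Acc, No): the test accuracy of a CNN trained on exactly the masked
channels (maximize) and the channel count (minimize). The loop is standard
elitist NSGA-II: fast non-dominated sorting, crowding distance, binary
tournament on (rank, crowding), uniform crossover (p = 0.9), per-gene
bit-flip mutation (p = 1/n_genes), and (μ+λ) survival. Populations hold 10
chromosomes; the run stops at a 100-generation cap or earlier when the
objective-space movement over the last 10 generations falls below 0.001
(checked at generations 10, 20, …). "Objective-space tolerance" is
operationalized as the maximum normalized change of the archive front's
ideal and nadir points over that window. All-zero
masks are repaired by switching on one uniformly random gene. Fitness is
cached by gene mask with a fixed training seed, so identical masks are
never retrained and a run is a deterministic function of its seed.

The reported front is the non-dominated set over *all* evaluated
chromosomes (archive front), summarized per channel count (best accuracy
per size, absent sizes blank) and, across subjects, as per-size
channel-coincidence tallies. An exhaustive enumerator
(`brute_force_pareto`, ≤ 12 channels) provides the exact front for oracle
tests.

## Synthetic data generator

Each synthetic subject has pink-noise background (1/f, σ = 10 µV) on all
channels. Informative channels additionally carry a band-limited sinusoid
whose amplitude is 2 µV × effect_size × max(0, rating − 5): 10 Hz (alpha)
on {C4, AF4, O1} for arousal, 20 Hz (beta) on the disjoint {PO3, Oz, Fp2}
for valence, so the two dimensions are separable tasks. Ratings are iid
uniform on [1, 9] by default; when exact class counts are requested they
are drawn from separated uniforms (low U(1.5, 4.5), high U(5.5, 8.5),
configurable). With effect_size = 0 the classes are statistically identical
and any classifier must sit at chance. The generator exists to make channel
recovery falsifiable; it deliberately omits physiological realism (no
EOG/EMG artifacts, no volume conduction, no inter-channel noise
correlation), so passing tests certify the pipeline's mechanics, not
performance on real EEG.

**Complementary planting.** With the redundant default, any single
informative channel can saturate accuracy once the effect is strong, and
the Pareto front collapses to one channel — a subset-recovery experiment
would then be vacuous. The `complementary` mode divides each expressing
trial into k contiguous time blocks (k = number of informative channels)
and plants the oscillation of block j on informative channel j only
(rotated per trial). A single channel then sees the cue in only 1/k of a
trial's segments, accuracy rises stepwise with the number of planted
channels covered (≈ 0.6 / 0.8 / 1.0 for k = 3 under the recovery
conditions below), and only the full planted set is sufficient.

## Desk-scale experiment profile

The end-to-end recovery experiment (in `eegsel.experiments`) runs, per
seed: an 8-channel montage subset (Fp1…T7) with arousal planted on
{F3, C3, T7}; 20 trials of 60 s, classes 10/10 with high ratings from
U(6.5, 8.5) (homogeneously strong bursts), effect_size 4, complementary
mode; 2-s segments; trial-level 50/25/25 split; tiny CNN trained 8 epochs;
NSGA-II with population 10 and at most 12 generations. One run takes on
the order of a minute on one CPU core. The run's outcome is the number of
planted channels appearing in the size-3 entry of the archive front; the
null control repeats the pipeline with effect_size = 0 and reports test
accuracy, which must sit at chance (0.5 ± 0.1).

These problem sizes are the package's own desk-scale study conditions; the
full-scale protocol (32 channels, 40 trials, 200 epochs, 100 generations)
is exposed by the default configuration values and runs unchanged, just
longer.

## Known limitations

- The synthetic signal model is a deliberate simplification; absolute
  accuracies on it say nothing about real-EEG accuracy.
- Fitness noise: a mask's accuracy is a single training run on a finite
  test set, so Pareto fronts on small cohorts fluctuate at the ±0.05
  level; under the recovery conditions the size-3 entry can occasionally
  be displaced by a lucky larger or smaller mask.
- Non-nested model selection in the classical baseline slightly
  optimistic-biases its reported accuracies.
- Segment-level splitting (the default, protocol-faithful mode) leaks
  within-trial correlation; use trial-level grouping for
  cross-trial-generalization claims.
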