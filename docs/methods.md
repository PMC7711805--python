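# Methods

## Problem and pipeline

The package detects a binary driving state — unfavorable (UDS, the
positive class) vs non-unfavorable (NUDS) — from event-locked multichannel
EEG. The analysis chain is: continuous 30-channel recording with event
markers → zero-phase FIR bandpass (0.01–70 Hz) → 1-s epochs (−100 to
+900 ms around each marker, half-open, so exactly 1000 samples at
1000 Hz) → per-epoch baseline correction over the pre-marker 100 ms →
rejection of epochs with any sample strictly beyond ±50 μV → per-channel
sample entropy → optional PCA reduction at a 95 % cumulative-variance
threshold → six classifiers under seeded stratified 10-fold
cross-validation → percent metrics, pooled out-of-fold ROC/AUC, and a
per-channel Mann–Whitney comparison table.

## Sample entropy

For series *u*(1..*N*): embed as *X*(*i*) = [*u*(*i*), …, *u*(*i*+*m*−1)].
*B* counts unordered pairs *i* ≠ *j* (both in 1..*N*−*m*) with Chebyshev
distance ≤ *r*; *A* counts the same pairs extended to length *m*+1;
SampEn = −ln(*A*/*B*). Conventions and their rationale:

- **Template range.** The classical formulation is ambiguous between
  *N*−*m* and *N*−*m*+1 templates at length *m*; this implementation uses
  the *N*−*m* templates that can be extended to length *m*+1 (the standard
  convention). The difference is O(1/*N*).
- **Defaults** *m* = 2, *r* = 0.2·SD of the individual epoch-channel
  series (`r_mode="sd_fraction"`), the Richman–Moorman convention. With a
  fractional tolerance SampEn is invariant under affine amplitude scaling;
  it is always invariant under additive offsets (up to floating-point
  rounding of shifted differences).
- **Undefined values.** If *A* = 0 or *B* = 0 the statistic is undefined;
  the estimator returns NaN rather than a large surrogate number, and
  batch extraction drops such rows with a logged count, keeping feature
  tables finite and auditable. A constant series is reported as 0 (every
  template matches every other at both lengths).
- **Fast path.** The estimator is a vectorized boolean-matrix formulation
  of the O(*N*²) pair count (~1 MB of workspace at *N* = 1000). Its
  correctness is pinned to literal double-loop transcriptions of the
  definitions in the test suite (agreement ≤ 1e−12 on dozens of seeded
  series).

Approximate entropy (Φ^m − Φ^(m+1), self-matches included, always finite)
and spectral entropy (Shannon entropy of the periodogram PSD over
0.5–70 Hz, base 2, normalized by log2 of the bin count to [0, 1]) are
provided as comparison features. Note the raw periodogram's exponential
bin fluctuations keep white-noise spectral entropy a few percent below
the flat-spectrum limit of 1.

## Synthetic data: what it emulates and what it does not

No recordings ship with the package; the generator is the data source,
at two fidelity levels.

**Feature level.** `generate_feature_table` draws per-channel SampEn
values i.i.d. from class-conditional Gaussians whose means/SDs are the
package's built-in 30-channel profile set (e.g. C3: 0.424 ± 0.127 under
UDS vs 0.534 ± 0.159 under NUDS). Twenty-five channels have lower SampEn
under UDS; five (FP2 — marginally, by 0.002 — F4, FC4, CP3, CP4) are
reversed. Gaussianity and channel independence are modeling assumptions
of the generator, not empirical claims: real EEG features are spatially
correlated across neighboring electrodes, so absolute classifier
accuracies on this generator do not transfer to real data, while rank
properties (separability direction, test calibration) do. The FP2
population gap is about one third of its sampling standard error at
n = 800/class, so its observed direction at study scale is close to a
coin flip — sign-pattern checks therefore either aggregate across
replicates or restrict to channels whose gap exceeds 4 standard errors.

**Signal level.** Epochs and continuous recordings are built from MIX(*p*)
processes: a unit-variance 10 Hz sinusoid (alpha band, physiologically
plausible carrier) whose samples are independently replaced with
probability *p* by uniform noise on [−√3, √3], scaled to 20 μV so the
clean signal stays inside the ±50 μV screen. SampEn increases
monotonically in *p*, and each channel/class *p* is an increasing affine
map of the profile mean (clipped to [0.05, 0.95]), so the *ordering* of
class SampEn per channel matches the profiles; absolute SampEn values are
not calibrated, since MIX has no closed-form SampEn. Recordings place
`events_per_condition` NUDS markers followed by the same number of UDS
markers at 1.5 s spacing (one block per task), over a MIX(0.5)
background.

**Imperfections injected.** Linear drift (default 0.2 μV/s) exercises
baseline correction, and with probability `artifact_rate` (default 0.05)
per marker window a rectangular 25 ms pulse at 100–150 μV is written onto
one random channel, with its position recorded for test assertions.
Pulses rather than single-sample spikes are used deliberately: a
one-sample delta is attenuated roughly sevenfold by the 70 Hz low-pass
and would no longer trip the downstream ±50 μV screen, whereas a 25 ms
pulse keeps most of its energy below the filter edge and survives.

## Numerical and design choices

- **FIR filter.** Linear-phase Hamming-window design applied as a single
  centered (zero-phase) convolution with reflect-padded edges. The tap
  count is set from the upper band edge (transition ≈ one tenth of
  70 Hz), giving ≥ 50 dB attenuation one octave above it. The 0.01 Hz
  high-pass edge is nominal: realizing a matching transition would need a
  filter longer than the recording, and on 1-s epochs such a high-pass is
  inert; the baseline-correction step is what removes slow offsets at
  epoch scale.
- **Amplitude screen.** Strict inequality (|x| > 50 μV rejects; exactly
  50 μV is kept) — the bound states the permitted extremes. A retention
  below 80 % raises a warning flag, mirroring the acquisition protocol's
  minimum acceptable yield.
- **PCA.** Centering without variance scaling (all 30 features share the
  SampEn scale). Retention: smallest *k* with cumulative explained ratio
  ≥ threshold (comparison padded by 1e−9 so a spectrum summing exactly to
  the threshold is kept). Loading signs are fixed by making each
  component's largest-magnitude element positive. By default PCA is
  refit inside each CV training fold (leakage-free); a `global` mode fits
  once on all data, matching the single reported decomposition of
  benchmark studies that tune on the full feature table.
- **Classifiers.** scikit-learn estimators behind a fixed-configuration
  facade: KNN with Euclidean metric and 1/d² vote weights (k selected
  over 2–10 by pooled CV accuracy, ties to the smaller k); decision tree
  with Gini impurity and best-first growth capped at 21 leaves (= 20
  splits); unpenalized logistic regression (C = ∞); SVMs with polynomial
  kernels of degree 1/2/3, box constraint 1, inverse-variance kernel
  scale, offset 1. Only the structural parameters are fixed; the rest are
  the conventional defaults of the reference environment such benchmarks
  are usually run in, and all are configurable. Continuous scores for ROC
  are class probabilities (KNN/DT/LR) or the signed decision value (SVM),
  oriented toward UDS.
- **Cross-validation.** Stratified 10-fold with seeded shuffling; with
  balanced 800/800 classes every test fold holds 80 epochs per class.
  Fold test sets partition the data; pooled confusion counts are fold
  sums; the ROC is computed once from pooled out-of-fold scores. An
  optional participant-grouped mode keeps all epochs of a subject in one
  fold — epoch-level CV with within-subject correlation risks optimistic
  estimates, and the option makes that distinction explicit without
  changing the default.
- **Metrics.** SEN = TP/(TP+FN), SPE = TN/(TN+FP), PRE = TP/(TP+FP),
  ACC = (TP+TN)/total, in percent. (A variant formulation of specificity
  with TP in the numerator circulates in the applied literature; it is
  inconsistent with precision and with reported degenerate classifier
  rows, so the standard TN-based form is used.) Zero-denominator ratios
  are NaN and flagged by name, never silently 0.
- **Channel comparison.** Two-sided Mann–Whitney U, asymptotic normal
  approximation with tie and continuity corrections — appropriate at
  n = 800 per class and matching the `<0.001` granularity such tables
  report. Significance is flagged at uncorrected p < 0.05, the
  presentation convention of per-channel tables; Bonferroni and
  Benjamini–Hochberg columns are emitted alongside for readers who want
  familywise or FDR control. The U statistic is validated against an
  exhaustive pair-count oracle for small samples with ties.
- **Determinism.** Every stage seed derives from the master seed via
  `SeedSequence`; reports are written with fixed float formats and sorted
  JSON keys, so same-seed runs are byte-identical (timings are logged
  separately). EDF output is 16-bit (quantization ≈ range/65535),
  validated by round-trip through an independent reader.

## Problem sizes

The default pipeline configuration reproduces the study scale
(16 × 50 × 2 = 1600 one-second 30-channel epochs at 1000 Hz) and runs in
a few minutes on one core; the test suite exercises the same code paths
at reduced sizes (fewer subjects/events, 250 Hz, shorter series) chosen
so each statistical check retains its power — e.g. oracle equivalence on
series up to N = 300, recovery of the channel direction pattern over 100
study-scale feature-table replicates, and CV sanity at 200–800 epochs per
class.

## Known limitations

- Feature-level draws ignore inter-channel correlation; signal-level MIX
  epochs match class ordering but not absolute SampEn values.
- Ocular-artifact handling is reduced to the amplitude criterion (an EOG
  regression hook would slot in before rejection); real blink/saccade
  morphology is not simulated.
- The EDF writer targets the subset of EDF+ needed here (one data-record
  duration, one annotation stream); it is validated against `mne`'s
  reader, not against every EDF consumer.
- Real-data accuracies from driving-simulator studies are not
  reproducible from synthetic features; the package's claims are about
  the pipeline's correctness and calibration, not about re-achieving any
  particular published accuracy.
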