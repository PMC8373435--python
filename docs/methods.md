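# Methods

This note documents the models and procedures implemented in `brs_eeg`, the
parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions needed to reproduce results exactly.

## Between-run similarity

The core statistic quantifies how much the spectral structure of
resting-state EEG changes between two runs recorded around a demanding
cognitive task. Per participant and scalp region:

1. Each run is band-pass filtered (0.5–50 Hz), segmented into 6-s epochs
   with 60 % overlap (36 epochs from a 90-s run), and epochs with absolute
   amplitude above 100 µV on any montage channel are dropped.
2. Each kept epoch × electrode yields seven band powers (delta 1–4, theta
   4–8, low alpha 8–10, high alpha 10–13, low beta 13–20, high beta 20–30,
   gamma 30–45 Hz).
3. Powers are averaged over the region's electrodes (unweighted mean),
   giving one 7-vector per epoch.
4. Every run-1 epoch is paired with every run-2 epoch; each pair is scored
   by the reciprocal Euclidean distance between vectors, and the raw
   similarity S is the mean over all n × m pairs. S is symmetric in the
   runs, homogeneous of degree −1 under a common power rescaling, and
   strictly decreasing in between-run displacement.
5. S is standardized against the healthy-control group:
   S̃ = (S − mean_HC)/std_HC, with the sample (n−1) standard deviation.

### Numerical conventions

* **Band power.** One-sided periodogram of the demeaned, Hann-tapered
  epoch; band power is the integral over bins with low ≤ f < high.
  Half-open bins count shared band edges (4, 8, 10, 13, 20, 30 Hz) exactly
  once. A unit-amplitude in-band sinusoid yields ≈ 0.5 µV²; the seven bands
  capture ≥ 85 % of the variance of a 0.5–50 Hz band-limited signal.
* **Distance floor.** The pairwise score 1/‖·‖ is undefined at zero
  distance, which cannot occur for noisy data but can for synthetic
  degenerate input; the distance is floored at ε = 10⁻¹², capping the score
  at 10¹². This guard is deterministic and documented rather than an error.
* **Filter.** Windowed-sinc (Hamming) FIR, odd tap count chosen for a
  one-way group delay of at most 0.5 s (501 taps at 500 Hz), applied
  forward–backward (zero phase, squared magnitude response). Stop-band
  rejection at 60 Hz is better than 20× in amplitude; pass-band ripple at
  10 Hz is within 5 %.
* **Epoch count.** floor((T − L)/step) + 1 with step = round(epoch·(1 −
  overlap)·rate) samples; the trailing partial window is discarded. 90 s at
  500 Hz / 6 s / 60 % gives exactly 36; rejection of a spiked epoch leaves
  35.
* **Standardization modes.** `global` (default) standardizes with all HCs,
  reproducing the conventional cohort-wide benchmark; `fold-train`
  recomputes the HC reference inside each cross-validation training fold
  and is the leakage-safe variant.

### Montage

Six regions over 30 electrodes of the 10–20 layout: frontal (FP1, FP2, F3,
F4, F7, F8, Fz), central (FC3, FC4, FCz, C3, C4, Cz), parietal (CP3, CP4,
CPz, P3, P4, Pz), occipital (O1, O2, Oz), left temporal (FT7, T3, TP7, T5),
right temporal (FT8, T4, TP8, T6). The occipital region is sometimes quoted
with Cz as its third electrode, which duplicates the central electrode and
leaves only 29 unique channels; we treat that as a transcription slip and
default to Oz, with `Montage.default(occipital_third="Cz")` available to
reproduce the literal 29-channel variant. Per-band analyses reuse the same
code path with a band subset of size one rather than a separate
implementation.

## Baseline single-run features

* **Spectral power**: per-electrode band power averaged over the run's
  epochs (7 features for the frontal region).
* **Katz fractal dimension**: the waveform as a planar curve with unit
  abscissa spacing; KFD = log₁₀(n)/(log₁₀(n) + log₁₀(d/L)) with L the curve
  length, d the maximal excursion from the first sample, n = N − 1. Unit
  spacing makes any affine series exactly 1; a constant series is defined
  as 1. Values for noise-like signals fall in (1, 2).
* **Coherence**: magnitude-squared coherence from Hann-tapered 1-s
  sub-windows with 50 % overlap inside each epoch, averaged over the band's
  bins, then over epochs; one feature per unordered electrode pair
  (n_e(n_e−1)/2, e.g. 21 frontal features). Single-segment coherence is
  refused because it is identically 1.

Only run-1 epochs feed these features, matching the single-run comparison
design.

## Classification and selection

* **LDA** is implemented in closed form: score(x) = (μ_P−μ_N)ᵗΣ⁻¹x − ½
  (μ_P−μ_N)ᵗΣ⁻¹(μ_P+μ_N) − ln(C_Pπ_N/(C_Nπ_P)), with empirical priors by
  default and equal class penalties (so the penalty term vanishes). The
  pooled covariance uses the n − 2 divisor. When its condition number
  exceeds 10⁸ (e.g. 21 coherence features on ~46 training participants),
  Ledoit–Wolf scalar shrinkage toward a scaled identity is applied
  automatically; with shrinkage disabled a singular covariance is an error.
* **SVM** is the standard soft-margin RBF machine (libsvm via
  scikit-learn), wrapped with a fixed ±1 label convention so decision-score
  signs are deterministic; the dual solution is cross-checked in the test
  suite against an independent quadratic-programming oracle.
* **LOPO-CV**: one fold per held-out participant; accuracy = correct/total,
  granularity 1/N (one flip at N = 50 is exactly 2 %).
* **Grid search**: exhaustive LOPO-CV over C, γ ∈ {2⁻²⁹, 2⁻²⁷, …, 2²⁹}
  (30 × 30 = 900 points by default; `ParamGrid.from_exponents` builds the
  31 × 31 alternative, and `ParamGrid.small()` is a reduced 10 × 10 grid
  with odd exponents −9…9 for desk-scale runs). Ties prefer the smallest C,
  then the smallest γ.
* **SFS**: greedy forward chain over the regional features, scored by
  LOPO-CV accuracy; step ties resolve to the earliest region in montage
  order. For the SVM, selection and hyperparameter search run together: a
  full chain is built per grid point and the global argmax over (grid
  point, prefix length) fixes both the subset and (C, γ). A search that
  reaches accuracy 1.0 stops early — under the strict-improvement tie rule
  no later candidate can replace it, so the short-circuit is exact.
* Reported SFS/grid accuracies are **validation accuracies**: the held-out
  participants take part in selecting the subset and hyperparameters. This
  matches the reference protocol, which is why the `fold-train`
  standardization and per-fold evaluation exist as the leakage-safe
  alternative. Under a zero-effect cohort the selected best accuracy is
  therefore biased above chance (see Limitations).

## Group statistics

Wilcoxon rank-sum (Mann–Whitney) contrasts of AD vs HC, MCI vs HC and AD vs
MCI per region, two-sided throughout. The exact null distribution is used
for combined samples of at most 20 without ties; otherwise the normal
approximation with tie and continuity corrections. Within each contrast the
per-test level is Bonferroni-corrected by the number of regions tested
(0.05/6 = 0.0083). A one-sample Kolmogorov–Smirnov screen against a normal
with the sample's estimated mean/SD documents the choice of a nonparametric
test; it never switches the test automatically, and without a Lilliefors
correction its p-values are conservative.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not clinical
realism:

* Each participant owns a per-region, per-band log-normal power profile
  around a resting-state-like baseline (delta 20, theta 10, low alpha 8,
  high alpha 6, low beta 4, high beta 2, gamma 1 µV²) with inter-subject
  spread 0.4 on the natural-log scale, drawn independently per region and
  band.
* Epoch-to-epoch powers fluctuate log-normally around the profile (jitter
  0.15).
* The run-2 profile is the run-1 profile shifted multiplicatively on power
  by exp(±magnitude), the sign random per participant × region × band, and
  the magnitude group- and band-specific. Defaults: 0.05 everywhere for
  HC; additionally 0.5 in low/high beta and gamma for the MCI-like group
  and 0.5 in delta and theta for the AD-like group, following the
  band-specific pattern expected of impaired groups. Effect sizes are not
  published for the reference cohort, so these magnitudes are chosen once
  for testability.
* Default cohort sizes mirror the reference study (27 HC / 24 MCI / 23 AD);
  any sizes are accepted.

Two fidelity levels share the same profiles and substreams: power vectors
drawn directly (fast), or raw multichannel signals built as sums of
band-limited Gaussian noise components with the profile variances
(exercising filtering and spectral estimation; epoch scatter then arises
from finite-sample estimation rather than injected jitter). A single cohort
seed drives one substream per participant keyed by participant index, so
adding a participant never changes the others' data.

What the generator does **not** model: 1/f background shape, ocular/EMG
artifacts (beyond an optional spike-injection helper for the rejector),
volume-conduction correlation between electrodes, or a shared per-subject
global power scale across regions. Passing tests therefore demonstrate
correct recovery of the *assumed* structure, not performance on real
recordings.

## Problem sizes used in the shipped checks

Unit and property tests run on small synthetic inputs (seconds). The
end-to-end checks use: 20 + 20 participants at power-vector fidelity with
the reduced 10 × 10 grid for SFS+SVM parameter recovery; a 74-participant
reference-scale cohort for the cohort-level counts, standardization
identity and group contrasts; and 50 replicate null cohorts (10 per group,
12 epochs) for the type-I-error check of the contrast stack.

## Known limitations

* The joint SFS × grid maximization reports a validation accuracy. Because
  LOPO folds share almost all training data, per-configuration accuracies
  under a null cohort are strongly correlated across folds and heavy-tailed,
  and the selected maximum over ~2,100 configurations typically lands
  around 0.65–0.85 at 20 participants/group even with zero group effect
  (a permuted-label control reproduces the same distribution). Treat the
  selected accuracy as optimistic; unbiased generalization estimates
  require nesting the whole selection inside an outer cross-validation,
  which is out of scope here.
* EDF ingestion requires the optional `mne` dependency; the package's text
  array format is the primary fixture path.
* Absolute band-power values depend on the declared taper/normalization
  conventions; comparisons across packages should use ratios or
  standardized quantities.
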