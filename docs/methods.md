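# Methods

`rigwatch` implements a smartwatch-accelerometer activity-recognition
pipeline for cable-logging rigging crews — choker setters (travel to log,
set choker, travel away, clear) and chasers (travel to log, unhook, travel
away, clear) — together with a work-cycle simulator that stands in for
field recordings, which are not distributable.  This note records the
models, the parameters that matter, and the design choices made where the
problem was genuinely open.

## Signal front end

Raw tri-axial acceleration arrives at a nominal 25 Hz in thousandths of
standard gravity (mgn).  Each axis is filtered with an order-8 (9-tap)
Hamming-windowed-sinc FIR bandpass before anything else happens; the
orientation-invariant magnitude

    A_mag = sqrt(A_x^2 + A_y^2 + A_z^2)

of the *filtered* axes is the single series all downstream features see.

Band edges are 0.5 and 0.9 **as fractions of the Nyquist frequency** —
the convention of `fir1`-style designers — i.e. 6.25–11.25 Hz at 25 Hz.
This is the only reading under which "0.5 and 0.9" are valid bandpass
edges without further scaling; a Hz interpretation remains selectable
(`FilterSpec.edges_in_hz`) for sensitivity experiments.  Two further
choices:

* **Exact DC/Nyquist nulls.**  A 9-tap windowed-sinc bandpass retains
  small residual gain at 0 (−0.015) and substantial gain at Nyquist
  (0.79).  A symmetric two-point correction `alpha + beta*(−1)^k` is
  subtracted from the coefficients so both gains are exactly zero while
  linear phase is preserved; the band-center gain moves to 1.168
  (+1.35 dB).  The DC null removes the 1000-mgn gravity offset entirely
  rather than to filter ripple.
* **Causal filtering.**  Forward-only convolution, as the filter would
  run on the watch; the first `order` samples are transient and returned
  flagged rather than trimmed, and windows overlapping the warm-up are
  kept.

At this order the filter is very leaky by design: a 2-Hz gait fundamental
passes at ~12% amplitude while broadband movement energy passes near
unity, so the magnitude series still separates movement regimes by
amplitude rather than acting as a narrowband detector (see
`results/filter_response.csv`).

## Labeling, windows, features

Time-study episodes are half-open intervals `[start, stop)`; a boundary
timestamp belongs to the episode that starts there, so consecutive
elements partition time with no double labeling.  Samples outside every
episode are `UNLABELED` and excluded from modeling (the element set is
exhaustive in the field protocol, so unlabeled samples only arise from
log gaps).  Timestamps are canonical integer epoch milliseconds; CSV
readers accept epoch-ms or ISO-8601.

Sliding windows are backward-looking with length `w = round(window_s *
rate_hz)` samples and step `max(1, round_half_up(w * (100 − overlap)/100))`
— e.g. a 3-s window at 25 Hz with 25% overlap advances 56 samples, and a
1-s window at 90% overlap advances 3 (round-half-up of 2.5).  Windows
never span session boundaries.

Ten time-domain features per window: mean, standard deviation, maximum,
minimum, median absolute deviation, mean absolute deviation, skewness,
interquartile range, range, excess kurtosis.  Estimator variants are
configurable because they differ across computing environments; defaults:

| feature | default estimator |
| --- | --- |
| sd | n−1 sample estimator |
| MAD (median) | 1.4826 × median absolute deviation about the median |
| MAD (mean) | unscaled mean absolute deviation about the mean |
| IQR | linear-interpolation (type-7) quantiles |
| skewness | g1 = m3/m2^1.5 (moment estimator) |
| kurtosis | g2 = m4/m2² − 3 (moment estimator, excess) |

Bias-adjusted G1/G2 variants and a raw MAD are selectable.  Zero-variance
segments define skewness and kurtosis as 0 so quiescent windows still
yield finite predictors.  Window labels are the majority vote of the
window's labeled samples; ties resolve to the latest sample whose label is
among the tied candidates; all-unlabeled windows are dropped.

## Predictor selection

The ten features are recomputed over each *whole activity episode*, and an
unscaled (covariance) PCA of that per-cycle table drives selection: the
smallest leading set of components whose cumulative variance exceeds 95%
is retained, and any feature with |loading| > 0.4 inside those components
becomes a predictor.  Unscaled PCA is deliberate: the amplitude summaries
(maximum, range) carry variance orders of magnitude above the shape
statistics, PC1 explains ~98% of variance, and exactly {maximum, range}
pass the loading rule — on the simulated sessions as in the field data.
Correlation-matrix PCA is available (`scaled=True`); the suite tests that
the unscaled rule is scale-sensitive, which is the honest cost of this
convention.

## Classifier and evaluation

Windows split 2/3 training / 1/3 testing at random within each class
(round-half-up per class), preserving the heavy class imbalance (73%
clear for choker setters, 93% for chasers).  The forest is a bagging loop
over CART trees: 150 trees, `m_try = floor(sqrt(p))` features per split,
and — the imbalance counter-measure — each tree's bootstrap draws the
same number of rows, with replacement, from every class: the training
count of the least common class (travel away for choker setters, travel
to log for chasers).  This per-class balanced bootstrap is why the forest
is hand-rolled over `sklearn` trees rather than using
`RandomForestClassifier`, which cannot stratify bootstraps this way nor
expose the per-tree out-of-bag votes needed for the OOB-accuracy-vs-trees
diagnostic.  Prediction is by majority vote; class scores are vote
fractions; score ties resolve to the fixed (sorted) class order.

Per-class metrics from the confusion matrix (rows = predicted, columns =
actual): sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP),
precision Pr = TP/(TP+FP), reported as percentages; F1 = 2·Pr·Se/(Pr+Se)
from the rates; balanced accuracy BA = (Se+Sp)/2 from the percentages.
Metrics for a class with no test instances are explicit missing values,
never zeros.  These definitions are pinned by an exact-reproduction test:
feeding the two published field confusion matrices through the metric
layer reproduces every cell of the corresponding published accuracy
tables to printed precision.

Model comparison uses the Hand-and-Till multiclass AUC: for each
unordered class pair (i, j), the Mann–Whitney probability that a random
class-i case outranks a random class-j case on the class-i score (ties
½), symmetrized and averaged over all pairs.  Vote fractions are the
score source; the AUC is invariant to any strictly monotone rescaling of
each score column, so this choice is mild.  The sweep evaluates the
window-size × overlap grid and selects the highest AUC, breaking ties
toward smaller windows, then larger overlaps.

## Validation splits and the overlap-leakage null

Two split modes are provided:

* `window` (default) — random per-class window-level split, replicating
  the field protocol;
* `episode` — whole contiguous same-label runs (≈ episodes) assigned to
  one side, so overlapping windows never straddle the split.

The distinction matters enormously.  At high overlap a test window shares
up to 90% of its samples with a training window; fully grown trees then
recognize the noise realization itself.  The package's no-signal null
(simulator `separability = 0`, every activity emitting one common noise
law) makes this measurable: under the episode-grouped split the
best-of-grid AUC is ~0.50–0.52 (chance), while under the window-level
split it reaches ~0.95 on pure noise (`analysis/05_null_calibration.py`,
`results/null_calibration.csv`).  Consequently the null calibration is
defined on the grouped split — under a leak-prone split it would measure
the leak, not the absence of signal — while the learnability checks keep
the window-level protocol for comparability with the field study.  Any
absolute accuracy obtained under window-level validation with overlapping
windows should be read with this leakage in mind.

## The simulator

The simulator generates what the downstream stages need and nothing more:
a labeled stream whose *cycle structure, duration distributions and class
imbalance* match the field summaries, with movement regimes that are
admitted inventions (the field study reports no signal-level description
of the activities).

**Durations** are lognormal, moment-matched per element to the published
mean/SD (positive, right-skewed, medians below means — consistent with
the published quartiles).  The choker-setter clear element (mean 220.31 s,
SD 519.17 s, CV 236%) makes any sample-SD check at moderate n nearly
powerless (the SD estimator's own SE is ~11% of its value at n = 50,000);
moment recovery for that element is therefore verified on the log scale,
where the matched (μ, σ) are estimated to a fraction of a percent.

**Cycle structure.**  The published per-element duration means and the
published activity time shares are jointly inconsistent with strict
4-element cycles (they would force an 81.4% clear share for choker
setters, not the observed 73.04%).  The two are reconciled by element
multiplicity: the implied episode frequencies (share_i / mean_i) show
choker setters performing ≈1.8 (travel to log, set choker) visits per
(travel away, clear) pair — they handle several chokers per turn — while
all four chaser elements occur equally often.  Cycles are therefore
generated as `k ×` (travel to log, set choker) + travel away + clear with
`k = 1 + Poisson(0.84)` for choker setters (`E[k] = 1.84` reproduces the
73.04% clear share exactly in expectation) and `k = 1` for chasers.  A
2000-cycle draw reproduces all eight published shares within half a
percentage point (`results/simulated_time_shares.csv`).

**Signal regimes** (all parameters exposed on `ActivityProfile`):

* *gait* (travel elements): per-axis sinusoid at the dominant stride
  frequency (2.0 Hz toward the log, 1.8 Hz away) with axis weights
  (1.0, 0.6, 0.35) × base amplitude (500 mgn toward, 260 mgn away, the
  loaded walk being the more energetic) plus Gaussian noise (120/60 mgn);
* *manipulation* (set choker / unhook): Poisson-timed (2 s⁻¹)
  sample-scale impulses with exponential amplitudes (mean 900 mgn),
  random sign and random axis distribution, plus 80-mgn noise — sharp
  pulses pass the bandpass nearly intact;
* *quiescent* (clear): 30-mgn noise with sporadic (0.1 s⁻¹) small pulses.

A `separability` dial in [0, 1] blends every activity toward one common
60-mgn noise law: 0 is the no-signal null, 1 the full contrast.  A
1000-mgn gravity offset sits on the z axis.  Episode boundaries fall on
sample boundaries, so timestamp labeling recovers the generating labels
exactly, and fixed seeds reproduce output files byte-identically.

What the simulator does **not** emulate — and hence what passing tests do
not show about field data: real wrist kinematics (harmonics, asymmetric
strides, posture drift), watch/phone clock offset, sensor dropouts, and
between-worker heterogeneity.  The end-to-end checks demonstrate that the
pipeline recovers a learnable regime structure under the field study's
imbalance and protocol, not that field accuracies are reproducible — those
depend on recordings that are not available.

## Problem sizes and numerical choices

The packaged experiments run a reduced grid ({1, 3, 5, 10} s ×
{0, 50, 90}% overlap) on 150-cycle sessions (~12 h of simulated signal,
~1.1 M samples; ~100 cycles for the null), sizes chosen so a full
experiment completes in about a minute on one CPU while spanning both
grid axes; the full 15 × 5 grid is available through the same functions
and the CLI.  All randomness flows from one master seed via spawned
`SeedSequence` children (simulator, split, per-tree bootstraps and
feature draws); per-tree seeds stay below 2³¹.  Feature extraction is
vectorized over a strided window view; near-constant windows whose
central moments underflow are treated as zero-variance.  Step and
per-class split counts round half-up; window counts obey
`floor((n − w)/step) + 1`.

## Known limitations

* The regime waveforms are invented; only durations, cycle structure and
  imbalance are anchored to published values.
* Window-level validation inflates accuracy at high overlap (quantified
  by the null experiment); grouped-split results are the conservative
  reading.
* No clock-drift model: stream and log share an exact time base, unlike
  field recordings from two devices.
* Skewness/kurtosis of constant windows are defined as 0, a modeling
  convenience rather than a statistical convention.
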