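# Methods

`tmvpa` implements a time-resolved multivariate decoding analysis for
epoched EEG, together with a synthetic-study generator that makes every
stage of the pipeline testable without any recorded data. This note
documents the model, the conventions the package fixes where the
analysis leaves a choice open, and what the synthetic data do and do
not establish.

## The analysis

**Preprocessing.** Raw epochs (µV, trials × channels × samples,
−100 to +500 ms around stimulus onset at 500 Hz) pass through four
stages in a fixed order:

1. *Artifact rejection* — a trial is dropped if any sample of any
   channel exceeds its role threshold in absolute value: ±25 µV on the
   horizontal EOG, ±60 µV on the vertical EOG, ±80 µV on any scalp
   channel. The comparison is strict (a sample exactly at the
   threshold survives). Rejection runs first because the thresholds
   are voltages and must see unnormalized data.
2. *Valid-trial selection* — only correct, target-present trials enter
   the decoding.
3. *Running-average smoothing* — a centered 20 ms boxcar. At 500 Hz
   this is 11 samples (the smallest odd count whose span covers
   20 ms); edge samples use the truncated window, i.e. the mean over
   however many samples the window actually overlaps.
4. *Baseline z-scoring* — per trial and channel, subtract the mean and
   divide by the SD of the baseline period (closed interval
   [−100, 0] ms). The SD uses the population convention
   (denominator *n*). A trial whose baseline is constant on any
   channel (SD < 1e−12) is excluded and logged in provenance.

Whether z-scoring precedes or follows smoothing is an open choice; the
package applies smoothing first and records the order in each
dataset's provenance so the alternative can be evaluated.

**Decoding.** At each post-onset sample the scalp-channel voltages
form one 32-dimensional feature vector per trial. Classification is a
linear soft-margin SVM (libsvm via scikit-learn, C = 1 on z-scored
inputs) inside a stratified 4-fold cross-validation with pseudo-trial
averaging: the trials of a class within a fold are averaged into one
pseudo-trial, the classifier is trained on the 3 training folds'
pseudo-trials (6 vectors) and tested on the held-out fold's 2, and the
whole assignment is redrawn 100 times ("fold permutations"), averaging
the accuracies. Each held-out fold therefore contributes an accuracy
in {0, 50, 100}%, and chance is 50% even when class counts are
unbalanced, because testing is per-class balanced by construction.
Both the pseudo-trial granularity (`pseudo_per_fold`) and whether the
test fold is pseudo-averaged (`pseudo_average_test`) are configurable;
the defaults are one pseudo-trial per class per fold on both sides.

Stratified assignment gives each class fold sizes differing by at most
one, with remainder trials distributed to folds in random order. Two
labelings are supported: *location* (left vs right target; run
separately within exemplar-search and category-search trials) and
*type* (exemplar vs category search, pooled over target sides). The
positive class (right / category) fixes the sign of the weight
vectors, which are averaged across folds and permutations; without a
fixed orientation the average would cancel.

**Summaries.** Per subject and condition: peak accuracy (maximum over
post-onset samples), latency to peak (earliest sample attaining the
maximum — the tie-break is ours, the analysis does not dictate one),
and mean accuracy over a closed analysis window (200–350 ms for
location decoding, 100–250 ms for type decoding).

**Activation patterns.** A linear classifier's weights are a backward
model; the forward-model (Haufe) transform `pattern = Σw / (wᵀΣw)`
projects them through the empirical channel covariance Σ of the same
single-time-point feature matrices that entered the decoding (all
trials, not pseudo-trials). Weights are rescaled to unit norm before
the transform, making the output invariant to positive rescaling —
the natural convention for a quantity reported in arbitrary units. An
unnormalized variant (`normalize=False`, plain Σw) is available.
Patterns are averaged over the analysis window and tested channel-wise
at group level (one-sample two-sided t vs 0, BH-FDR across channels at
α = 0.05).

**Statistics.** Accuracy-vs-chance uses per-time-point one-sample
t-tests (two-sided by default; the one-sided alternative is a flag),
corrected over time points by BH-FDR and Holm–Bonferroni (both always
computed; FDR is the default decision rule). Group comparisons of
accuracy time courses use a permutation test: observed Welch
(unequal-variance) t per time point; the null reshuffles subjects'
group labels, the same shuffle at every time point so within-subject
temporal structure survives under the null; 10,000 permutations;
one-sided empirical p with add-one smoothing, p = (1 + #{t* ≥ t_obs}) /
(1 + N), so p is never exactly 0 and the smallest attainable value is
1/(1+N). Summary quantities get BCa bootstrap intervals
(10,000 resamples; bias constant from the bootstrap distribution's
fraction below the plug-in estimate, acceleration from jackknife
skewness — computed by `scipy.stats.bootstrap(method="BCa")` behind
the package API, with a guard that collapses a degenerate bootstrap
distribution to the point interval [c, c]). Paired exemplar-vs-category
and Welch group contrasts round out the inferential layer; mixed-effects
modelling is deliberately out of scope.

## The synthetic generator

The generator produces a two-group study (defaults: 21 "human" and 20
"nonhuman" subjects; 154 target-present trials per task × side cell;
~85% correct responses; 5% artifact-injected trials) from an explicit
forward model. Per trial,

    V[c, t] = Σ_e A_e(task, group) · g_e(t) · P_e[c] + ε[c, t],

where each effect *e* has a unit-norm scalp topography `P_e`, a
Gaussian temporal envelope `g_e` (center, SD in ms) and a µV amplitude
per task × group cell. A lateralized effect applies `P_e` as given to
right-target trials and its left-right mirror to left-target trials;
the montage is schematic (symmetric 2-D positions for a 32-channel
10-20 layout that includes PO7/PO8, plus HEOG/VEOG), because only
mirror symmetry and neighborhood structure matter to the pipeline.

Noise ε is zero-mean Gaussian with a squared-exponential spatial
correlation over the schematic positions (length-scale 0.5, one knob
for topography smoothness) and lag-1 autoregressive temporal structure
(coefficient 0.9 per sample, one knob for EEG-like autocorrelation),
normalized so `noise_sd` (default 1 µV) is the marginal per-channel,
per-sample SD. Artifact trials receive large Gaussian-bump EOG
deflections (80 µV HEOG / 150 µV VEOG, alternating), guaranteed to trip
the rejection thresholds. Every subject draws from an independent
stream keyed by (master seed, group, subject index), so simulation
order cannot change any subject's data.

Two default effects emulate the phenomenology of visual search for
face targets:

- *target_selection* — lateralized posterior topography (contralateral
  positivity over PO8/P8/O2 and mirror negativity), envelope centered
  at 250 ms (SD 35 ms); amplitude 0.55 µV in exemplar cells and
  0.35 µV in category cells, identical across groups. This drives
  left-vs-right location decoding, more strongly for exemplar search.
- *task_signature* — non-lateralized posterior-midline topography,
  envelope centered at 190 ms (SD 12 ms); amplitude 0.65 µV (human) /
  0.35 µV (nonhuman) in exemplar cells, 0 in category cells. This
  makes search type decodable from ~175 ms with a stronger effect in
  the human-face group.

The amplitudes were calibrated once against the default noise so that
the pipeline lands in the intended qualitative regime — exemplar
location-decoding peaks in the low–mid 90s (%), category decoding
clearly lower, type decoding above chance from ~175 ms and stronger in
the human group — and then frozen. No recorded dataset informs these
numbers, so agreement with any real study's exact accuracies is not
claimed and not tested.

**What the generator does not emulate.** Volume conduction from real
sources, non-Gaussian and non-stationary noise, eye-movement dynamics
(artifacts are threshold-trippers, nothing more), drifting alertness,
continuous (non-epoched) data, or realistic electrode geometry.
Passing tests therefore establish that the *pipeline* is correct and
well-calibrated under its own assumptions — not that those assumptions
hold for any particular recording.

## Numerical conventions and degenerate inputs

- Peak/latency ties break to the earliest post-onset sample.
- Threshold comparisons are strict; window intervals are closed.
- A degenerate SVM training set (identical pseudo-trials across
  classes) scores at chance with zero weights and a warning instead of
  failing.
- Zero-variance cells in t-tests are flagged: p = 1 when the mean
  equals the null value, 0 otherwise.
- The BCa interval of a constant sample is [c, c], flagged degenerate.
- Welch df follows Welch–Satterthwaite; the permutation test's Welch t
  is defined as 0 where both groups have zero variance at a time point.

## Problem sizes in the validation suite

The test and acceptance experiments run reduced designs chosen for
adequate statistical power at manageable cost: null-calibration
studies use 20 subjects and decode 50 post-onset time points (every
5th sample of a 500 Hz simulation — simulating at a lower rate with
the same lag-1 AR coefficient would lengthen the physical noise
correlation time and is avoided deliberately) with 3 fold
permutations; the effect-recovery experiments use 8–20 subjects,
30–100 trials per cell, 2–10 fold permutations, and decimated time
grids (every 4th–10th sample). The paired exemplar-vs-category and
group-effect experiments use 100 trials per cell, close to the
≈112 valid trials per class of the emulated study, because per-subject
peak estimates at much lower trial counts are dominated by max-statistic
noise. Resampling calibrations use 500–1000 Monte-Carlo replicates and
the full 10,000 bootstrap resamples.

## Known limitations

- The SVM regularization constant (C = 1) is a convention on z-scored
  inputs, not a tuned value; the analysis is insensitive to it at the
  pseudo-trial SNRs involved, but the config exposes it.
- Accuracy quantization ({0, 50, 100}% per fold) makes per-time-point
  distributions coarse at few fold permutations; group-level tests
  treat them as continuous, which is standard but approximate.
- BCa intervals for the mean undercover slightly at n = 20 (≈94%
  observed for a 95% nominal level) — a property of the estimator, not
  of this implementation.
- The N2pc utility computes the contralateral-minus-ipsilateral
  difference at PO7/PO8 only; it is a descriptive companion, with no
  inferential layer attached.
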