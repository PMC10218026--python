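# Methods

This note documents the models, algorithmic choices, and limitations of the
`serialdep` pipeline in enough detail to reproduce or audit any stage.

## Behavioral model and psychometric fitting

Responses in the discrimination task are modeled as Bernoulli draws from a
lapse-corrected cumulative Gaussian, ψ(x) = λ/2 + (1 − λ)Φ((x − μ)/σ), where
x is the probe magnitude in task units (dots, ms, or px). The lapse ("finger
error") rate λ is fixed at 0.05 and split equally between floor and ceiling,
so ψ ranges over [λ/2, 1 − λ/2]; λ is not estimated. Fitting maximizes the
binomial log-likelihood over (μ, log σ): a coarse 61 × 41 grid over μ
(levels span ± half a span) and σ (span/50 to 3 × span, geometric) seeds a
Nelder–Mead refinement (xatol 1e-7, fatol 1e-10). Unit tests pin the result
to an independent brute-force grid search. Degenerate data (all responses 0
or all 1) return a boundary estimate flagged non-converged; fits whose μ
falls outside the probe range are flagged as boundary fits. Fits use the
linear magnitude axis; PSEs are reported in raw stimulus units.

Derived quantities: PSE = μ (the Gaussian median); JND = σ·z* with
Φ(z*) = (0.75 − λ/2)/(1 − λ), i.e. the probe distance between the 50% and
75% points of the *lapse-corrected* curve (for λ = 0.05, z* ≈ 0.7169);
WF = JND/PSE. The serial-dependence index is
(PSE_high − PSE_low)/PSE_low × 100, computed per subject and dimension after
splitting trials by the low/high level of that inducer dimension
(marginalizing the other dimensions, which cancel in the balanced
factorial). Trials without a response are excluded from all behavioral fits.

The trial-level "nonlinear regression" is realized as a binomial GLM with
logit link (the canonical model for 0/1 responses). The response is recoded
so 1 = "reference greater", and the probe plus the three inducer magnitudes
enter as ratios to the reference constants (16 dots, 200 ms, 6 px) — the
probe as well, for scale comparability, although only the inducers require
it. Under this convention a positive inducer coefficient is attractive.
Perfect separation is caught and flagged rather than silently reported.

## Synthetic designs and observer

The generator reproduces both experimental structures:

- **Discrimination sessions**: full 2 (inducer numerosity 12/24 dots) ×
  2 (duration 140/280 ms) × 2 (dot size 4/8 px) × 5 (probe level) factorial,
  n repetitions per cell (default 10 → 400 trials, in blocks of 40). Probe
  levels are {8,12,16,24,32} dots, {100,140,200,280,400} ms, or
  {3,4,6,8,12} px by task. The session total of 400 fixes the per-cell count
  at 10 under the full crossing.
- **Passive streams**: all 27 combinations of 3 × 3 × 3 magnitudes
  ({12,16,24} dots, {140,200,280} ms, {4,6,8} px) repeated equally (default
  80 → 2,160 trials in 8 blocks), with 10 reduced-contrast (×0.7) catch
  trials per 270-trial block (3.7%). Each trial carries the previous trial's
  magnitudes as its past labels; the stream's first trial has no predecessor
  and is flagged unusable. Catch trials are drawn from the 27 standard
  combinations so the per-combination count stays exact.

The simulated observer's PSE shifts by ± half the per-dimension bias
according to each inducer level, so the full low-to-high PSE difference
equals the bias; a target effect index E% is converted exactly to a bias via
b = E·p/(100 + E/2). `default_observer(task)` encodes group-scale
parameters: Weber fractions 0.12/0.17/0.07 and effect indices
3.42/0.92/7.58% for the numerosity/duration/size tasks, with the bias
confined to the task dimension.

## Epoch simulator

Epochs span −200 to 700 ms at 250 Hz (configurable; the span must be an
integer number of samples). Each epoch is the sum of:

1. a class-independent evoked template (triphasic Gaussian components at
   100/170/250 ms, amplitudes +2/−2.5/+1.5, widths 20/30/40 ms), scaled per
   channel by a fixed 0.5–1.5 gradient;
2. the past-magnitude signal: for each dimension, sign(past level) ×
   subject amplitude × window amplitude, projected through a unit-norm
   per-dimension topography (default: fixed seeded random directions) and
   confined to the configured latency windows. Three-level past labels map
   to −1/0/+1 (the intermediate level carries no signal);
3. noise that is AR(1) in time (lag-1 coefficient 0.9 by default,
   stationary variance normalized to noise_sd²) and spatially mixed by a
   random per-subject matrix, so channels are correlated and channel
   selection/window averaging are non-trivial.

Defaults (32 channels, 250 Hz) are a desk-scale stand-in for a 32-channel
laboratory montage; the simulator makes no attempt at forward-model realism
— no continuous raw signal, no blinks/artifacts, no volume conduction
geometry. Consequently, passing recovery tests demonstrate the *analysis
chain* is unbiased and sensitive under plausible SNR, not that effect sizes
transfer to real recordings.

Cohorts draw each subject's signal amplitude from N(mean, sd) truncated at
zero and set the behavioral effect to intercept + slope × amplitude +
N(0, noise). The default coupling (intercept 2%, slope 30%/unit, noise
1.5%, amplitude 1 ± 0.4) is chosen so that between-subject effect variance
comfortably exceeds psychometric fitting noise at 200–400 trials per
subject, making the brain–behavior link recoverable at desk-scale cohort
sizes; it is deliberately larger than the group-average effect sizes the
observer defaults emulate.

## Decoding

Per dimension, epochs are partitioned into low/high past-magnitude classes
(other dimensions marginalized; intermediate past levels dropped). Features
are mean amplitudes in 100 ms windows stepped by 20 ms; a window covers
samples in [start, start + length), and the grid holds
floor((span − length)/step) + 1 windows (41 for a −200..700 ms epoch).

Per iteration (default 30), each class's trials are randomly partitioned
into pseudo-trials of k trials (k defaults to floor(n/10) clipped to
[10, 20]; the remainder is discarded), keeping n_pseudo (default 10) per
class. Cross-validation leaves one pseudo-trial per class out per fold. Per
fold and window: the top-5 channels by one-way ANOVA F (ties broken toward
lower channel index; zero-variance channels get F = 0) are selected on the
training fold, features are z-scored with training-fold statistics, and a
linear SVM (C = 1, the kernel/regularization being unstated in common
toolboxes' defaults) classifies the held-out pair. CA per window is the
mean over folds, then over iterations. The master seed derives
per-iteration seeds as seed + iteration, so each iteration is independently
reproducible; identical seeds give bit-identical results.

The null variant permutes the training labels within each fold (drawn from
the same iteration stream) and is otherwise identical; its CA is the
empirical chance level used in the one-sample tests. Temporal
generalization trains at each window and tests at every window using the
same folds, channel selection, and (training-window) scaling, which makes
its diagonal reproduce the sliding-window result exactly at the same seed.

Latency-window summaries (early 50–200 ms, late 500–650 ms) average CA over
windows *fully contained* in the interval — the conservative reading; with
the standard grid the early window comprises the windows starting at 60,
80, and 100 ms.

## Brain–behavior link and cluster permutation

Per window, Eff ∼ CA + (1 | Subj) is fitted across subjects. The study
design provides one (Eff, CA) pair per subject, making the random-intercept
variance unidentifiable; the fit therefore reduces to the OLS solution
(slope, t, two-sided p, and R² — marginal R² by construction). When
subjects contribute repeated observations, a random-intercept mixed model
(REML) is used and marginal R² is reported. Windows where CA has zero
variance across subjects return NaN statistics rather than failing.

Clusters are maximal runs of ≥ 2 consecutive windows with p < 0.05 (no
per-window multiplicity correction — the cluster stage is the control).
Each cluster is validated separately: per permutation, the effects are
shuffled across subjects and the CA at each cluster window is shuffled
independently across subjects (the within-cluster reading of the
procedure), the regression is refit per cluster window, and the permutation
succeeds if it yields a contiguous run of ≥ cluster-length windows with
|t| ≥ the cluster's own minimum |t| (two-sided). The reported p uses the
add-one estimator (successes + 1)/(n_perm + 1), which cannot return zero.

A calibration caveat, measured in the test suite: because only the
cluster's own windows are refit and the threshold is the cluster's own
minimum |t|, permuted null data rarely reproduce a cluster, so nearly every
cluster that forms by chance is called significant. The family-wise error
of the whole procedure is therefore governed by the probability of *forming*
a ≥2-window run at α = 0.05 (≈ 7–9% on a 41-window grid with independent
windows, more when neighboring windows correlate), not by the nominal 5%.
The permutation p is best read as cluster-conditional evidence, not as a
family-wise-corrected p.

## Statistical utilities

t tests use the exact t distribution (one-tailed = upper tail); Cohen's d
is the mean difference over the SD of the differences (paired/one-sample).
BH-FDR is the step-up adjustment with enforced monotonicity, validated
against an independent implementation. The power analysis scans n upward
using the exact noncentral-t power (df = n − 1, noncentrality d√n) and
returns the smallest n reaching the target; d = 0.55 at one-tailed α = 0.05
and power 0.9 gives n = 30 (power 0.9025; n = 29 reaches only 0.8933).

## Problem sizes used in the test suite

The suite exercises the full pipeline at desk scale, chosen to keep a
single-core run around four minutes: null-decoding calibration uses 10
subjects × 200 trials × 8 channels with 30 iterations; effect-index
recovery uses 100 simulated observers × 400 trials; cluster-permutation
calibration uses 200 null repetitions at 500 permutations, and coupling
recovery 12 subjects with 8 decoding iterations and 1,000 permutations.
Sharper recoveries (and the reported group effect sizes) would require
cohort sizes and permutation counts at the scale of the original study
design (30 subjects, 10,000 permutations), which the same code handles —
only runtimes grow.

## Known limitations

- The generator's evoked template and topographies are schematic; no
  attempt is made to model realistic scalp physics, artifacts, or
  non-stationary noise.
- Only two-class decoding of binarized past magnitudes is implemented (no
  multiclass or continuous decoding), matching the analysis it implements.
- The LME is degenerate by design with one observation per subject; R²
  should be compared across windows, not interpreted as a mixed-model
  conditional R².
- Repeated-measures/mixed ANOVAs on the exported tables are out of scope;
  the tidy CSVs are one call away from any standard ANOVA routine.
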