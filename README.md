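# serialdep

Analysis pipeline for **serial dependence in magnitude perception** and its
electrophysiological signature: psychometric estimation of perceptual
history biases, time-resolved multivariate decoding of past-stimulus
information from multichannel evoked epochs, and a cluster-permutation-
protected per-window regression linking decoding accuracy to the behavioral
bias. A synthetic-data generator emulating both experimental designs (an
inducer–reference–probe discrimination task and a passive magnitude
stream) makes every stage testable by parameter recovery.

Intended for psychophysicists and cognitive neuroscientists who want a
tested, reusable implementation of this analysis chain — either on
synthetic cohorts with known ground truth or on their own trial tables
(CSV) and epoched recordings (HDF5) in the documented formats.

## The analyses

**Behavior.** Two-alternative forced-choice responses per probe level are
fitted by maximum likelihood with a lapse-corrected cumulative Gaussian

&nbsp;&nbsp;&nbsp;&nbsp;ψ(x) = λ/2 + (1 − λ)·Φ((x − μ)/σ),&nbsp;&nbsp;λ = 0.05 fixed,

giving the PSE (μ), the JND (probe distance between the 50% and 75% points
of ψ), and the Weber fraction JND/PSE. Splitting trials by the low/high
magnitude of the preceding task-irrelevant *inducer* yields the serial-
dependence effect index **Eff = (PSE_high − PSE_low)/PSE_low × 100** (positive
= attractive). A trial-level binomial-logit regression of the response on
the probe and the three inducer magnitudes (coded as ratios to the
reference: 16 dots / 200 ms / 6 px) quantifies each dimension's pull.

**Decoding.** Epochs time-locked to an identical reference stimulus are
sorted by the *past* magnitude (low vs high). Within each 100 ms window
(20 ms steps), trials averaged into pseudo-trials (k = 10–20) are
classified with a linear SVM under leave-one-pseudo-trial-out
cross-validation; channel selection (top-5 ANOVA F) and z-scoring use the
training folds only, the whole procedure repeats over 30 random partitions,
and the mean classification accuracy (CA) per window is the readout. The
identical pipeline with shuffled training labels sets the chance level
empirically. Temporal generalization (train at one latency, test at
another) probes pattern stability.

**Brain–behavior link.** Per window, the model **Eff ∼ CA + (1 | Subj)**
is fitted across subjects (with one observation per subject it reduces to
the OLS fixed-effect solution). Runs of ≥ 2 consecutive significant windows
form clusters, validated by a within-cluster permutation test (effects and
per-window CA shuffled across subjects, 10,000 permutations by default,
threshold = the cluster's own minimum |t|).

Support utilities include paired/one-sample t tests with Cohen's *d*,
Benjamini–Hochberg FDR, Pearson correlation, and an exact noncentral-t
power analysis (d = 0.55, one-tailed α = 0.05, power 0.9 → n = 30).

## Worked example

The numbered scripts under `analysis/` run a desk-scale demo cohort
(6 subjects, 200 trials each, 8-channel epochs at 250 Hz, past-magnitude
signal injected at 50–200 and 500–650 ms, behavioral effect coupled to each
subject's signal amplitude):

```bash
cd analysis
python 01_simulate.py            # cohort + ground truth
python 02_fit_behavior.py        # psychometric fits, effect indices, regression
python 03_decode.py              # SVM decoding + shuffled-label null (~2 min)
python 04_link_brain_behavior.py # per-window Eff ~ CA, clusters, permutation
python 05_report.py              # assembled report
```

`02_fit_behavior.py` prints (this run's actual output):

```
Mean PSE by inducer level and serial-dependence effect (%):
            pse_low  pse_high     eff     wf
dimension
duration     15.732    16.068   2.122  0.131
numerosity   14.111    17.464  24.456  0.107
size         15.995    15.958  -0.260  0.136
```

Only the task-relevant dimension (numerosity) carries a generative bias in
the demo, and only there does the PSE shift — the fitted effect (24.5% on
average) tracks each subject's generative effect. `03_decode.py` then shows
above-chance CA for the injected signal (e.g. late-window numerosity CA
0.711 vs empirical chance 0.542), and `04_link_brain_behavior.py` finds the
windows where CA predicts the behavioral effect:

```
Clusters surviving the permutation test:
 dimension  start_ms  end_ms  length  min_abs_t  perm_p  n_perm
numerosity     340.0   360.0       2     3.0695    0.01    1000
```

A cluster of two consecutive windows whose CA predicts Eff across subjects,
with a within-cluster permutation p of 0.01 — at 6 subjects the localization
is coarse; recovery sharpens with cohort size (see `tests/test_acceptance.py`).

The same stages are available as a CLI (`serialdep simulate|fit-behavior|
decode|link|run-all|report`, configured by a JSON file mirroring
`RunConfig`), and all stage outputs are plain CSV/JSON/HDF5 files, so any
stage can be re-run in isolation or fed externally produced inputs.

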