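"""Null-calibration runs: the decoding pipeline applied to signal-free cohorts.

The shuffled-label decoding of epochs that contain no class-dependent signal
defines the pipeline's empirical chance level; averaged over windows and
subjects it must sit at 50% for the procedure to be unbiased.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from serialdep.decoding import DecodingParams, null_decode_timecourse, sort_epochs_by_past
from serialdep.params import CouplingParams, EEGSimParams, ObserverParams
from serialdep.simulate import simulate_cohort


def null_decoding_mean_ca(n_subjects: int = 10, seed: int = 0,
                          n_channels: int = 8, n_reps_per_cell: int = 5,
                          n_iterations: int = 30, dimension: str = "numerosity",
                          ) -> np.ndarray:
    """Per-subject mean shuffled-label CA on a zero-signal cohort.

    Simulates ``n_subjects`` subjects whose epochs contain no
    past-magnitude-dependent component (signal amplitude fixed at zero,
    AR(1) noise only), runs the full shuffled-label decoding
    (leave-one-pseudo-trial-out linear SVM, 10 pseudo-trials of 10 trials
    per class, ``n_iterations`` iterations) and returns each subject's CA
    averaged over all analysis windows.
    """
    eeg = EEGSimParams(
        n_channels=n_channels,
        signal_windows=((50.0, 200.0, {dimension: 0.0}),))
    coupling = CouplingParams(slope=0.0, intercept=0.0, noise_sd=0.0,
                              amplitude_mean=0.0, amplitude_sd=0.0)
    cohort = simulate_cohort(n_subjects, ObserverParams(), eeg, coupling,
                             seed=seed, task=dimension,
                             n_reps_per_cell=n_reps_per_cell)
    params = DecodingParams(pseudo_k=10, n_pseudo=10, n_iterations=n_iterations)
    out = np.empty(n_subjects)
    for i, sub in enumerate(cohort):
        ep0, ep1 = sort_epochs_by_past(sub.epochs, dimension)
        res = null_decode_timecourse(
            ep0, ep1,
            params=dataclasses.replace(params, seed=seed + 1000 * (i + 1)))
        out[i] = res.ca.mean()
    return out
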