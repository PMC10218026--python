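import numpy as np
import pytest

import serialdep as sd
from serialdep.params import EEGSimParams, ObserverParams


@pytest.fixture(scope="session")
def exp1_table():
    """400-trial numerosity session from a moderately biased observer."""
    table = sd.generate_design_exp1("numerosity", n_reps_per_cell=10, seed=11)
    obs = ObserverParams(pse_base=16.0, sigma=2.7, lapse=0.05,
                         bias_per_dimension={"numerosity": 1.6})
    return sd.simulate_responses(table, obs, seed=12)


@pytest.fixture(scope="session")
def short_eeg():
    """Small, fast epoch simulator: 6 channels, short epochs, one signal window."""
    return EEGSimParams(
        n_channels=6, sampling_rate=250.0, epoch_start=-100.0, epoch_end=300.0,
        signal_windows=((100.0, 250.0, {"numerosity": 1.0}),),
        noise_sd=1.0, noise_ar1=0.5, seed=21)


@pytest.fixture(scope="session")
def signal_epochs(short_eeg):
    """Epochs with a strong past-numerosity signal at 100-250 ms, 40 trials/class."""
    table = sd.generate_design_exp1("numerosity", n_reps_per_cell=2, seed=22)
    return sd.simulate_epochs(table.iloc[:80], short_eeg, subject_amplitude=2.0)


@pytest.fixture(scope="session")
def null_epochs(short_eeg):
    """Epochs with no class-dependent signal (amplitude zero)."""
    table = sd.generate_design_exp1("numerosity", n_reps_per_cell=2, seed=23)
    return sd.simulate_epochs(table.iloc[:80], short_eeg, subject_amplitude=0.0)
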