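"""Shared demo-run configuration for the numbered analysis scripts.

Desk-scale version of the study: 6 subjects, 200 trials each (numerosity
task), 8-channel epochs at 250 Hz with a past-magnitude signal in the early
(50-200 ms) and late (500-650 ms) latency windows, and a positive coupling
between each subject's signal amplitude and their behavioral
serial-dependence effect.
"""

from pathlib import Path

from serialdep import DecodingParams
from serialdep.params import CouplingParams, EEGSimParams
from serialdep.pipeline import RunConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "runs" / "demo"


def demo_config() -> RunConfig:
    return RunConfig(
        n_subjects=6,
        task="numerosity",
        dimensions=("numerosity", "duration", "size"),
        n_reps_per_cell=5,
        eeg=EEGSimParams(
            n_channels=8,
            signal_windows=(
                (50.0, 200.0, {"numerosity": 0.10, "duration": 0.10, "size": 0.10}),
                (500.0, 650.0, {"numerosity": 0.15, "duration": 0.15, "size": 0.15}),
            )),
        coupling=CouplingParams(slope=30.0, intercept=2.0, noise_sd=1.5,
                                amplitude_mean=1.0, amplitude_sd=0.4),
        decoding=DecodingParams(pseudo_k=10, n_pseudo=10, n_iterations=6),
        n_perm=1000,
        seed=2024,
    )
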