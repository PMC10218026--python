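"""Parameter containers for the synthetic observer, EEG simulator, and brain-behavior coupling."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Magnitude dimensions manipulated in both experiments.
DIMENSIONS = ("numerosity", "duration", "size")

#: The three active discrimination tasks (experiment 1).
TASKS = ("numerosity", "duration", "size")

#: Constant reference stimulus: 16 dots, 200 ms, 6 px dot radius.
REFERENCE = {"numerosity": 16.0, "duration": 200.0, "size": 6.0}

#: Two-level inducer magnitudes used in experiment 1.
EXP1_INDUCER_LEVELS = {
    "numerosity": (12, 24),
    "duration": (140, 280),
    "size": (4, 8),
}

#: Five probe levels per task (experiment 1).
PROBE_LEVELS = {
    "numerosity": (8, 12, 16, 24, 32),
    "duration": (100, 140, 200, 280, 400),
    "size": (3, 4, 6, 8, 12),
}

#: Three-level magnitudes of the passive stream (experiment 2); the middle
#: level of each dimension coincides with the experiment-1 reference.
EXP2_LEVELS = {
    "numerosity": (12, 16, 24),
    "duration": (140, 200, 280),
    "size": (4, 6, 8),
}

#: Catch (oddball) stimuli are shown at 30% reduced contrast.
CATCH_CONTRAST = 0.7


@dataclass
class ObserverParams:
    """Generative parameters of a biased two-alternative forced-choice observer.

    The observer compares a probe magnitude against an internal estimate of
    the reference whose point of subjective equality (PSE) is shifted by the
    magnitudes of the preceding inducer: for each dimension ``d`` with a
    high-level inducer the PSE moves by ``+bias_per_dimension[d] / 2`` (in
    probe units), and by the negative half for a low-level inducer, so the
    full low-to-high PSE difference equals the stated bias.

    Parameters
    ----------
    pse_base
        Unbiased PSE, in probe units (defaults to the reference magnitude).
    sigma
        Slope of the cumulative-Gaussian psychometric function, probe units.
    lapse
        Stimulus-independent error probability in [0, 1], split equally
        between floor and ceiling of the psychometric function.
    bias_per_dimension
        Signed full PSE shift per inducer dimension, probe units.
    """

    pse_base: float = REFERENCE["numerosity"]
    sigma: float = 2.7
    lapse: float = 0.05
    bias_per_dimension: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must lie in [0, 1], got {self.lapse}")
        for dim, b in self.bias_per_dimension.items():
            if dim not in DIMENSIONS:
                raise ValueError(f"unknown bias dimension {dim!r}")
            if not math.isfinite(b):
                raise ValueError(f"bias for {dim!r} must be finite, got {b}")


def default_observer(task: str) -> ObserverParams:
    """Observer parameters emulating the reported group-average behavior.

    Weber fractions of roughly 0.12 / 0.17 / 0.07 and serial-dependence
    effect indices of roughly 3.4% / 0.9% / 7.6% for the numerosity,
    duration, and size tasks, with the bias confined to the task-relevant
    inducer dimension.
    """
    wf = {"numerosity": 0.12, "duration": 0.17, "size": 0.07}[task]
    eff = {"numerosity": 3.42, "duration": 0.92, "size": 7.58}[task]
    pse = REFERENCE[task]
    # JND = sigma * z* with Phi(z*) = (0.75 - lapse/2)/(1 - lapse); lapse 5%.
    z_star = 0.7168917  # Phi^-1(0.725/0.95)
    sigma = wf * pse / z_star
    bias = effect_to_bias(eff, pse)
    return ObserverParams(pse_base=pse, sigma=sigma, lapse=0.05,
                          bias_per_dimension={task: bias})


def effect_to_bias(effect_percent: float, pse_base: float) -> float:
    """Invert the serial-dependence index to a generative PSE shift.

    With PSE_low = p - b/2 and PSE_high = p + b/2, the effect index
    ``(PSE_high - PSE_low) / PSE_low * 100`` equals ``b / (p - b/2) * 100``;
    solving for ``b`` gives the exact generative shift for a target index.
    """
    return effect_percent * pse_base / (100.0 + effect_percent / 2.0)


@dataclass
class EEGSimParams:
    """Parameters of the multichannel evoked-epoch simulator.

    Epochs span ``epoch_start``..``epoch_end`` ms around stimulus onset at
    ``sampling_rate`` Hz. Each epoch is the sum of a class-independent evoked
    template, a past-magnitude-dependent component confined to
    ``signal_windows`` and projected through per-dimension unit-norm
    ``signal_topography`` vectors, and spatially mixed AR(1) noise.

    ``signal_windows`` is a sequence of ``(start_ms, end_ms, amplitudes)``
    where ``amplitudes`` maps dimension name to a nonnegative amplitude.
    """

    n_channels: int = 32
    sampling_rate: float = 250.0
    epoch_start: float = -200.0
    epoch_end: float = 700.0
    evoked_template: np.ndarray | None = None
    signal_windows: Sequence[tuple[float, float, Mapping[str, float]]] = (
        (50.0, 200.0, {"numerosity": 0.3, "duration": 0.3, "size": 0.3}),
        (500.0, 650.0, {"numerosity": 0.5, "duration": 0.5, "size": 0.5}),
    )
    signal_topography: Mapping[str, np.ndarray] | None = None
    noise_sd: float = 1.0
    noise_ar1: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.epoch_start < 0.0 < self.epoch_end):
            raise ValueError("epoch must bracket stimulus onset: epoch_start < 0 < epoch_end")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError(f"noise_ar1 must lie in [0, 1), got {self.noise_ar1}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for start, end, amps in self.signal_windows:
            if end <= start:
                raise ValueError(f"signal window ({start}, {end}) is empty")
            for dim, a in dict(amps).items():
                if dim not in DIMENSIONS:
                    raise ValueError(f"unknown signal dimension {dim!r}")
                if a < 0:
                    raise ValueError(f"signal amplitude for {dim!r} must be >= 0")

    @property
    def time_ms(self) -> np.ndarray:
        """Sample timestamps: first sample at epoch_start, last at epoch_end."""
        dt = 1000.0 / self.sampling_rate
        n = round((self.epoch_end - self.epoch_start) / dt)
        if not np.isclose(self.epoch_start + n * dt, self.epoch_end):
            raise ValueError("epoch span must be an integer number of samples")
        return self.epoch_start + dt * np.arange(n + 1)

    def topography(self, dimension: str) -> np.ndarray:
        """Unit-norm channel weight vector of one dimension's past-magnitude signal.

        Defaults to a fixed seeded random direction per dimension so that the
        three dimensions occupy distinct channel subspaces.
        """
        if self.signal_topography is not None:
            v = np.asarray(self.signal_topography[dimension], dtype=float)
            if v.shape != (self.n_channels,):
                raise ValueError("topography length must equal n_channels")
        else:
            rng = np.random.default_rng(7000 + DIMENSIONS.index(dimension))
            v = rng.normal(size=self.n_channels)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("topography vector must be nonzero")
        return v / nrm

    def template(self) -> np.ndarray:
        """Class-independent evoked waveform, one value per sample.

        Defaults to a canonical triphasic visual-evoked shape (P1-N1-P2-like
        Gaussian components at 100 / 170 / 250 ms).
        """
        t = self.time_ms
        if self.evoked_template is not None:
            v = np.asarray(self.evoked_template, dtype=float)
            if v.shape != t.shape:
                raise ValueError("evoked_template length must match the epoch grid")
            return v
        bumps = ((100.0, 20.0, 2.0), (170.0, 30.0, -2.5), (250.0, 40.0, 1.5))
        out = np.zeros_like(t)
        for center, width, amp in bumps:
            out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        return out


@dataclass
class CouplingParams:
    """Generative link between subject-level signal amplitude and behavioral effect.

    The per-subject behavioral serial-dependence index (in %) is drawn as
    ``intercept + slope * amplitude + N(0, noise_sd)``, where ``amplitude``
    is the subject's past-magnitude signal amplitude drawn from
    ``N(amplitude_mean, amplitude_sd)`` truncated at zero.
    """

    slope: float = 30.0
    intercept: float = 2.0
    noise_sd: float = 1.5
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
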