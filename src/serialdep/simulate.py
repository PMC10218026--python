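"""Synthetic designs, observer responses, and multichannel epochs with known ground truth.

Every downstream stage of the pipeline (psychometric fitting, decoding,
brain-behavior linking) is testable by parameter recovery against the
generative quantities produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from serialdep.epochs import EpochSet
from serialdep.params import (
    CATCH_CONTRAST,
    CouplingParams,
    DIMENSIONS,
    EEGSimParams,
    EXP1_INDUCER_LEVELS,
    EXP2_LEVELS,
    ObserverParams,
    PROBE_LEVELS,
    REFERENCE,
    TASKS,
    effect_to_bias,
)

EXP1_BLOCK_SIZE = 40  # 10 blocks of 40 trials = the 400-trial session


def generate_design_exp1(task: str, n_reps_per_cell: int = 10, seed: int = 0,
                         subject: int = 0) -> pd.DataFrame:
    """Randomized full-factorial inducer x probe design for one task condition.

    The 2 (inducer numerosity) x 2 (duration) x 2 (dot size) x 5 (probe
    level) factorial is repeated ``n_reps_per_cell`` times and shuffled,
    giving 40 x n_reps trials (400 at the default 10 repetitions per cell).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if n_reps_per_cell < 1:
        raise ValueError("n_reps_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    cells = [
        (num, dur, size, probe)
        for num in EXP1_INDUCER_LEVELS["numerosity"]
        for dur in EXP1_INDUCER_LEVELS["duration"]
        for size in EXP1_INDUCER_LEVELS["size"]
        for probe in PROBE_LEVELS[task]
    ]
    rows = np.repeat(np.arange(len(cells)), n_reps_per_cell)
    rows = rng.permutation(rows)
    arr = np.array(cells, dtype=float)[rows]
    n = len(rows)
    block = (np.arange(n) // EXP1_BLOCK_SIZE if n % EXP1_BLOCK_SIZE == 0
             else np.zeros(n, dtype=int))
    return pd.DataFrame({
        "subject": subject,
        "block": block,
        "trial": np.arange(n),
        "task": task,
        "inducer_numerosity": arr[:, 0],
        "inducer_duration": arr[:, 1],
        "inducer_size": arr[:, 2],
        "probe": arr[:, 3],
        "is_catch": False,
        "contrast": 1.0,
        "response": np.nan,
    })


def generate_design_exp2(n_blocks: int = 8, reps_per_combo: int = 80,
                         catch_per_block: int = 10, seed: int = 0,
                         subject: int = 0) -> pd.DataFrame:
    """Passive 3x3x3 magnitude stream with low-contrast catch trials.

    All 27 combinations of numerosity x duration x dot size appear exactly
    ``reps_per_combo`` times in randomized order (2,160 trials at the
    default 80 repetitions), split into ``n_blocks`` blocks each containing
    ``catch_per_block`` reduced-contrast catch trials. Each trial carries
    the previous trial's magnitudes as its past-magnitude labels; the first
    trial of the stream has no predecessor and is flagged unusable.
    """
    total = 27 * reps_per_combo
    if total % n_blocks != 0:
        raise ValueError(f"{total} trials cannot be split into {n_blocks} equal blocks")
    per_block = total // n_blocks
    if catch_per_block > per_block:
        raise ValueError("catch_per_block exceeds the trials per block")
    rng = np.random.default_rng(seed)
    combos = [
        (num, dur, size)
        for num in EXP2_LEVELS["numerosity"]
        for dur in EXP2_LEVELS["duration"]
        for size in EXP2_LEVELS["size"]
    ]
    rows = rng.permutation(np.repeat(np.arange(27), reps_per_combo))
    arr = np.array(combos, dtype=float)[rows]
    block = np.arange(total) // per_block
    is_catch = np.zeros(total, dtype=bool)
    for b in range(n_blocks):
        pick = rng.choice(per_block, size=catch_per_block, replace=False)
        is_catch[b * per_block + pick] = True
    df = pd.DataFrame({
        "subject": subject,
        "block": block,
        "trial": np.arange(total),
        "task": "passive",
        "numerosity": arr[:, 0],
        "duration": arr[:, 1],
        "size": arr[:, 2],
        "is_catch": is_catch,
        "contrast": np.where(is_catch, CATCH_CONTRAST, 1.0),
        "response": np.nan,
    })
    for dim in DIMENSIONS:
        df[f"past_{dim}"] = df[dim].shift(1)
    df["usable"] = np.r_[False, np.ones(total - 1, dtype=bool)]
    return df


def _trial_pse(table: pd.DataFrame, obs: ObserverParams) -> np.ndarray:
    """Per-trial PSE: base plus half the bias, signed by each inducer level."""
    pse = np.full(len(table), obs.pse_base)
    for dim, bias in obs.bias_per_dimension.items():
        low, high = EXP1_INDUCER_LEVELS[dim]
        lv = table[f"inducer_{dim}"].to_numpy()
        sign = np.where(lv == high, 1.0, np.where(lv == low, -1.0, 0.0))
        pse = pse + sign * bias / 2.0
    return pse


def simulate_responses(table: pd.DataFrame, obs: ObserverParams, seed: int = 0,
                       miss_rate: float = 0.0) -> pd.DataFrame:
    """Draw Bernoulli "probe greater" responses from the biased observer.

    The response probability is the lapse-corrected cumulative Gaussian
    ``lapse/2 + (1 - lapse) * Phi((probe - PSE_trial) / sigma)`` where the
    trial PSE is shifted by half the per-dimension bias according to each
    inducer level. ``response == 1`` codes "probe greater than reference".
    A fraction ``miss_rate`` of responses is set missing (NaN), emulating
    trials without a response.
    """
    if "probe" not in table.columns or table["task"].iloc[0] not in TASKS:
        raise ValueError("simulate_responses requires an active-task design with a probe")
    rng = np.random.default_rng(seed)
    pse = _trial_pse(table, obs)
    p = obs.lapse / 2.0 + (1.0 - obs.lapse) * ndtr(
        (table["probe"].to_numpy() - pse) / obs.sigma)
    out = table.copy()
    resp = (rng.random(len(table)) < p).astype(float)
    if miss_rate > 0:
        resp[rng.random(len(table)) < miss_rate] = np.nan
    out["response"] = resp
    return out


def _past_signs(labels: np.ndarray) -> np.ndarray:
    """Map past-magnitude labels to -1 (low extreme), +1 (high extreme), 0 otherwise."""
    finite = labels[np.isfinite(labels)]
    sign = np.zeros(labels.shape)
    if finite.size == 0:
        return sign
    lo, hi = finite.min(), finite.max()
    if lo == hi:
        return sign
    sign[labels == lo] = -1.0
    sign[labels == hi] = 1.0
    return sign


def simulate_epochs(table: pd.DataFrame, eeg: EEGSimParams,
                    subject_amplitude: float = 1.0) -> EpochSet:
    """Multichannel epochs carrying a latency-localized past-magnitude signal.

    Each epoch is the sum of

    - the class-independent evoked template (scaled per channel),
    - for each dimension, ``sign(past level) * subject_amplitude *
      window_amplitude`` projected through the dimension's unit-norm
      topography, nonzero only inside the configured signal windows,
    - temporally AR(1), spatially mixed Gaussian noise.

    The trial table must carry past-magnitude labels: either explicit
    ``past_<dim>`` columns (passive stream) or ``inducer_<dim>`` columns
    (discrimination design), which become the epochs' past labels.
    """
    t = eeg.time_ms
    n_time = t.size
    n_trials = len(table)
    nch = eeg.n_channels

    labels = {}
    for dim in DIMENSIONS:
        if f"past_{dim}" in table.columns:
            labels[dim] = table[f"past_{dim}"].to_numpy(dtype=float)
        elif f"inducer_{dim}" in table.columns:
            labels[dim] = table[f"inducer_{dim}"].to_numpy(dtype=float)
    if not labels:
        raise ValueError("trial table carries no past-magnitude labels")

    for start, end, _ in eeg.signal_windows:
        if start < t[0] or end > t[-1]:
            raise ValueError(f"signal window ({start}, {end}) outside the epoch span")

    rng = np.random.default_rng(eeg.seed)
    # Class-independent evoked response, graded across channels.
    chan_gain = np.linspace(0.5, 1.5, nch)
    epochs = np.broadcast_to(
        chan_gain[None, :, None] * eeg.template()[None, None, :],
        (n_trials, nch, n_time)).copy()

    # Past-magnitude-dependent component.
    for dim, lab in labels.items():
        sign = _past_signs(lab)
        if not np.any(sign):
            continue
        topo = eeg.topography(dim)
        amp_t = np.zeros(n_time)
        for start, end, amps in eeg.signal_windows:
            a = dict(amps).get(dim, 0.0)
            amp_t[(t >= start) & (t < end)] += a
        epochs += (sign[:, None, None] * subject_amplitude
                   * topo[None, :, None] * amp_t[None, None, :])

    # AR(1) noise with a random spatial mixing matrix (shared across trials).
    if eeg.noise_sd > 0:
        mix = rng.normal(size=(nch, nch)) / np.sqrt(nch)
        innov_sd = eeg.noise_sd * np.sqrt(1.0 - eeg.noise_ar1 ** 2)
        z = rng.normal(scale=innov_sd, size=(n_trials, nch, n_time))
        z = np.einsum("ij,tjk->tik", mix, z)
        noise = np.empty_like(z)
        noise[:, :, 0] = z[:, :, 0] / np.sqrt(1.0 - eeg.noise_ar1 ** 2)
        for s in range(1, n_time):
            noise[:, :, s] = eeg.noise_ar1 * noise[:, :, s - 1] + z[:, :, s]
        epochs += noise

    meta_cols = {f"past_{dim}": lab for dim, lab in labels.items()}
    meta = pd.DataFrame({"trial": np.arange(n_trials), **meta_cols})
    if "usable" in table.columns:
        meta["usable"] = table["usable"].to_numpy()
    return EpochSet(data=epochs, time_ms=t, sampling_rate=eeg.sampling_rate,
                    trial_meta=meta)


@dataclass
class SubjectData:
    """One simulated subject: design + responses, epochs, and generative truth."""

    subject: int
    table: pd.DataFrame
    epochs: EpochSet
    amplitude: float
    true_effect: float
    observer: ObserverParams


def simulate_cohort(n_subjects: int, obs: ObserverParams, eeg: EEGSimParams,
                    coupling: CouplingParams, seed: int = 0,
                    task: str = "numerosity", coupling_dimension: str | None = None,
                    n_reps_per_cell: int = 10) -> list[SubjectData]:
    """Cohort with a known amplitude-to-behavior coupling.

    Per subject, a past-magnitude signal amplitude is drawn from the
    coupling's amplitude distribution (truncated at zero); the behavioral
    serial-dependence effect (in %) is set to
    ``intercept + slope * amplitude + noise`` and converted exactly to the
    generative PSE shift on ``coupling_dimension`` (default: the task
    dimension). Responses and epochs are generated consistently, and the
    generative truth is returned alongside the data.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    dim = coupling_dimension or task
    out = []
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=(n_subjects, 3))
    for s in range(n_subjects):
        rng = np.random.default_rng(sub_seeds[s, 0])
        amplitude = max(0.0, rng.normal(coupling.amplitude_mean, coupling.amplitude_sd))
        effect = (coupling.intercept + coupling.slope * amplitude
                  + rng.normal(0.0, coupling.noise_sd))
        biases = dict(obs.bias_per_dimension)
        biases[dim] = effect_to_bias(effect, obs.pse_base)
        sub_obs = replace(obs, bias_per_dimension=biases)
        table = generate_design_exp1(task, n_reps_per_cell=n_reps_per_cell,
                                     seed=int(sub_seeds[s, 1]), subject=s)
        table = simulate_responses(table, sub_obs, seed=int(sub_seeds[s, 1]) + 1)
        sub_eeg = replace(eeg, seed=int(sub_seeds[s, 2]))
        epochs = simulate_epochs(table, sub_eeg, subject_amplitude=amplitude)
        out.append(SubjectData(subject=s, table=table, epochs=epochs,
                               amplitude=amplitude, true_effect=effect,
                               observer=sub_obs))
    return out
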