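"""Time-resolved multivariate decoding of past-stimulus magnitude from epochs.

The procedure mirrors standard evoked-response MVPA practice: trials are
sorted into two classes by the magnitude of the preceding stimulus,
averaged into pseudo-trials to raise SNR, reduced to the most informative
channels by a univariate ANOVA on the training folds, and classified with a
linear support vector machine under leave-one-pseudo-trial-out
cross-validation, separately within each 100 ms window stepped at 20 ms.
The whole procedure is repeated over iterations with fresh random
pseudo-trial partitions; a shuffled-label variant of the identical pipeline
provides the empirical chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from serialdep.epochs import EpochSet
from serialdep.params import DIMENSIONS


@dataclass
class WindowGrid:
    """Sliding analysis windows indexed by start time.

    A window covers samples with timestamps in ``[start, start + length)``.
    """

    starts: np.ndarray
    length: float = 100.0
    step: float = 20.0

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        if self.starts.size > 1 and not np.allclose(np.diff(self.starts), self.step):
            raise ValueError("window starts must be spaced by the step size")

    @classmethod
    def for_epochs(cls, epochs: EpochSet, length: float = 100.0,
                   step: float = 20.0) -> "WindowGrid":
        """Maximal grid inside the epoch span: floor((span - length)/step) + 1 windows."""
        t0, t1 = epochs.time_ms[0], epochs.time_ms[-1]
        span = t1 - t0
        if length > span:
            raise ValueError("window length exceeds the epoch span")
        n = int(np.floor((span - length) / step + 1e-9)) + 1
        return cls(starts=t0 + step * np.arange(n), length=length, step=step)

    @property
    def n_windows(self) -> int:
        return self.starts.size


@dataclass
class DecodingParams:
    """Tunable knobs of the decoding procedure.

    ``pseudo_k`` (trials averaged per pseudo-trial) defaults to
    ``floor(n_class_trials / 10)`` clipped to [10, 20]; ``n_pseudo`` is the
    number of pseudo-trials per class entering the leave-one-out loop.
    A master ``seed`` derives per-iteration seeds as ``seed + iteration``.
    """

    pseudo_k: int | None = None
    n_pseudo: int | None = 10
    n_iterations: int = 30
    n_keep: int = 5
    C: float = 1.0
    seed: int = 0


@dataclass
class DecodingResult:
    """Per-window classification accuracy with iteration bookkeeping."""

    ca: np.ndarray
    per_iteration: np.ndarray
    grid: WindowGrid
    is_null: bool
    pseudo_k: int
    n_pseudo: int
    n_iterations: int
    n_keep: int
    seed: int


@dataclass
class TemporalGeneralizationMatrix:
    """Train-window x test-window classification accuracy."""

    ca: np.ndarray
    per_iteration: np.ndarray
    grid: WindowGrid
    is_null: bool

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.ca)


def sort_epochs_by_past(epochs: EpochSet, dimension: str) -> tuple[EpochSet, EpochSet]:
    """Partition epochs into low/high past-magnitude classes for one dimension.

    Other dimensions are marginalized. With three-level past labels (passive
    stream), trials whose past level is intermediate are excluded, as are
    trials without a defined predecessor.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    col = f"past_{dimension}"
    if col not in epochs.trial_meta.columns:
        raise ValueError(f"epochs carry no past labels for {dimension!r}")
    lab = epochs.trial_meta[col].to_numpy(dtype=float)
    finite = np.unique(lab[np.isfinite(lab)])
    if finite.size < 2:
        raise ValueError(f"past labels for {dimension!r} do not form two classes")
    lo, hi = finite.min(), finite.max()
    ep_lo, ep_hi = epochs.subset(lab == lo), epochs.subset(lab == hi)
    if ep_lo.n_trials == 0 or ep_hi.n_trials == 0:
        raise ValueError("a past-magnitude class is empty after filtering")
    return ep_lo, ep_hi


def window_average(epochs: EpochSet, grid: WindowGrid) -> np.ndarray:
    """Mean amplitude per trial, channel, and window -> (trials, channels, windows)."""
    t = epochs.time_ms
    weights = np.zeros((t.size, grid.n_windows))
    for w, start in enumerate(grid.starts):
        mask = (t >= start) & (t < start + grid.length)
        if not mask.any():
            raise ValueError(f"window starting at {start} ms contains no samples")
        weights[mask, w] = 1.0 / mask.sum()
    return epochs.data @ weights


def _partition_average(features: np.ndarray, k: int, rng: np.random.Generator,
                       n_groups: int | None = None) -> np.ndarray:
    perm = rng.permutation(features.shape[0])
    avail = features.shape[0] // k
    n_groups = avail if n_groups is None else n_groups
    if n_groups > avail:
        raise ValueError(f"cannot form {n_groups} pseudo-trials of size {k} "
                         f"from {features.shape[0]} trials")
    idx = perm[: n_groups * k].reshape(n_groups, k)
    return features[idx].mean(axis=1)


def make_pseudotrials(features: np.ndarray, k: int, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      n_groups: int | None = None) -> np.ndarray:
    """Average a random disjoint partition of one class's trials into groups of k.

    The remainder (trials beyond the last full group of ``k``) is discarded.
    With ``k = 1`` the pseudo-trials are the original trials in permuted
    order.
    """
    features = np.asarray(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if features.shape[0] < k:
        raise ValueError(f"class has {features.shape[0]} trials, fewer than k={k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _partition_average(features, k, rng, n_groups)


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per column of X for the grouping y.

    Zero-variance columns get F = 0; columns with zero within-group variance
    but distinct group means get F = inf (perfectly informative).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.unique(y)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in groups:
        Xg = X[y == g]
        mg = Xg.mean(axis=0)
        ssb += Xg.shape[0] * (mg - grand) ** 2
        ssw += ((Xg - mg) ** 2).sum(axis=0)
    df_b = len(groups) - 1
    df_w = X.shape[0] - len(groups)
    msb = ssb / df_b
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F[msw == 0] = np.where(msb[msw == 0] > 0, np.inf, 0.0)
    return F


def select_channels(train_features: np.ndarray, labels: np.ndarray,
                    n_keep: int) -> np.ndarray:
    """Indices of the ``n_keep`` largest-F channels on the training set.

    Ties are broken in favor of the lower channel index; the returned
    indices are sorted ascending.
    """
    F = anova_f_scores(train_features, labels)
    if n_keep > F.size:
        raise ValueError("n_keep exceeds the number of channels")
    order = np.lexsort((np.arange(F.size), -F))
    return np.sort(order[:n_keep])


def _auto_pseudo_k(n_min: int) -> int:
    return int(np.clip(n_min // 10, 10, 20))


def _resolve_sizes(n0: int, n1: int, params: DecodingParams) -> tuple[int, int]:
    k = params.pseudo_k if params.pseudo_k is not None else _auto_pseudo_k(min(n0, n1))
    avail = min(n0, n1) // k
    n_pseudo = params.n_pseudo if params.n_pseudo is not None else avail
    n_pseudo = min(n_pseudo, avail)
    if n_pseudo < 2:
        raise ValueError("fewer than 2 pseudo-trials per class; reduce pseudo_k "
                         "or provide more trials")
    return k, n_pseudo


def _run_decoding(epochs0: EpochSet, epochs1: EpochSet, grid: WindowGrid | None,
                  params: DecodingParams, null: bool, tg: bool):
    if epochs0.n_trials == 0 or epochs1.n_trials == 0:
        raise ValueError("both classes must be non-empty")
    if grid is None:
        grid = WindowGrid.for_epochs(epochs0)
    F0 = window_average(epochs0, grid)
    F1 = window_average(epochs1, grid)
    k, n_pseudo = _resolve_sizes(F0.shape[0], F1.shape[0], params)
    nw = grid.n_windows
    shape = (params.n_iterations, nw, nw) if tg else (params.n_iterations, nw)
    per_iter = np.zeros(shape)
    yte = np.array([0, 1])
    for it in range(params.n_iterations):
        rng = np.random.default_rng(params.seed + it)
        P0 = _partition_average(F0, k, rng, n_pseudo)
        P1 = _partition_average(F1, k, rng, n_pseudo)
        correct = np.zeros((nw, nw) if tg else nw)
        for f in range(n_pseudo):
            tr = np.delete(np.arange(n_pseudo), f)
            Xtr_all = np.concatenate([P0[tr], P1[tr]])  # (2*(n_pseudo-1), nc, nw)
            ytr = np.repeat([0, 1], n_pseudo - 1)
            if null:
                ytr = rng.permutation(ytr)
            Xte_all = np.stack([P0[f], P1[f]])  # (2, nc, nw)
            for w in range(nw):
                Xtr = Xtr_all[:, :, w]
                sel = select_channels(Xtr, ytr, params.n_keep)
                mu = Xtr[:, sel].mean(axis=0)
                sd = Xtr[:, sel].std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                clf = SVC(kernel="linear", C=params.C)
                clf.fit((Xtr[:, sel] - mu) / sd, ytr)
                if tg:
                    # Test the window-w classifier on every test window,
                    # scaling with the training-window statistics.
                    Xte = (Xte_all[:, sel, :] - mu[:, None]) / sd[:, None]
                    flat = Xte.transpose(0, 2, 1).reshape(-1, sel.size)
                    pred = clf.predict(flat).reshape(2, nw)
                    correct[w] += (pred == yte[:, None]).sum(axis=0)
                else:
                    pred = clf.predict((Xte_all[:, sel, w] - mu) / sd)
                    correct[w] += (pred == yte).sum()
        per_iter[it] = correct / (2.0 * n_pseudo)
    ca = per_iter.mean(axis=0)
    if tg:
        return TemporalGeneralizationMatrix(ca=ca, per_iteration=per_iter,
                                            grid=grid, is_null=null)
    return DecodingResult(ca=ca, per_iteration=per_iter, grid=grid, is_null=null,
                          pseudo_k=k, n_pseudo=n_pseudo,
                          n_iterations=params.n_iterations, n_keep=params.n_keep,
                          seed=params.seed)


def decode_timecourse(epochs0: EpochSet, epochs1: EpochSet,
                      grid: WindowGrid | None = None,
                      params: DecodingParams = DecodingParams()) -> DecodingResult:
    """Sliding-window leave-one-pseudo-trial-out linear-SVM decoding.

    Per iteration a fresh pseudo-trial partition is drawn; per fold one
    pseudo-trial per class is held out, channel selection and feature
    standardization are computed on the training fold only, and the held-out
    pair is classified within each window. Per-window CA is the mean over
    folds, and the final CA the mean over iterations.
    """
    return _run_decoding(epochs0, epochs1, grid, params, null=False, tg=False)


def null_decode_timecourse(epochs0: EpochSet, epochs1: EpochSet,
                           grid: WindowGrid | None = None,
                           params: DecodingParams = DecodingParams()) -> DecodingResult:
    """Shuffled-label variant of :func:`decode_timecourse`.

    Training labels are permuted within each fold, destroying the class
    information while preserving every other property of the pipeline; the
    output serves as the empirical chance level.
    """
    return _run_decoding(epochs0, epochs1, grid, params, null=True, tg=False)


def temporal_generalization(epochs0: EpochSet, epochs1: EpochSet,
                            grid: WindowGrid | None = None,
                            params: DecodingParams = DecodingParams(),
                            null: bool = False) -> TemporalGeneralizationMatrix:
    """Train at each window, test at every window (same folds, selection, scaling).

    The matrix diagonal reproduces :func:`decode_timecourse` exactly for the
    same seed, because the random draws are identical.
    """
    return _run_decoding(epochs0, epochs1, grid, params, null=null, tg=True)


def window_mean_ca(result: DecodingResult, t_start: float, t_end: float) -> float:
    """Mean CA over windows fully contained in ``[t_start, t_end]``.

    A window qualifies when its whole extent ``[start, start + length)``
    lies inside the interval.
    """
    grid = result.grid
    mask = (grid.starts >= t_start) & (grid.starts + grid.length <= t_end)
    if not mask.any():
        raise ValueError(f"no window fully inside [{t_start}, {t_end}] ms")
    return float(result.ca[mask].mean())
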