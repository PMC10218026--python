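"""Linking decoding accuracy to the behavioral serial-dependence effect.

Per analysis window, the behavioral effect (one value per subject, in %) is
regressed on the window's classification accuracy with the mixed model
``Eff ~ CA + (1 | Subj)``. The study design yields a single (Eff, CA) pair
per subject, in which case the random-intercept variance is unidentifiable
and the fit degrades gracefully to the ordinary least-squares solution,
whose slope t, p, and (marginal) R-squared are reported. Runs of at least
two consecutive significant windows form clusters, each validated by a
within-cluster permutation test: effects are shuffled across subjects and
the CA at each cluster window is shuffled independently, the model is refit
per window, and a permutation succeeds when it produces an equally long
contiguous run of |t| values at or above the cluster's own minimum |t|.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LMEWindowStats:
    """Slope of Eff ~ CA at one analysis window."""

    window: float
    slope: float
    t: float
    p: float
    r_squared: float
    n_subjects: int


@dataclass
class Cluster:
    """Contiguous run of significant windows plus its permutation p-value."""

    indices: np.ndarray
    windows: np.ndarray
    length: int
    min_abs_t: float
    perm_p: float | None = None
    n_perm: int | None = None


def _ols_stats(effects: np.ndarray, cas: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple regression: slope, t, two-sided p, R^2."""
    n = effects.size
    res = stats.linregress(cas, effects)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return res.slope, t, res.pvalue, res.rvalue ** 2


def fit_effect_ca_lme(effects, cas, subjects=None, window: float = np.nan) -> LMEWindowStats:
    """Fit ``Eff ~ CA + (1 | Subj)`` for one window.

    With one observation per subject (the default: ``subjects`` omitted or
    all distinct) the random intercept is unidentifiable and the model
    reduces to OLS, reported with the fixed-effect slope t, p, and marginal
    R-squared. When subjects contribute repeated observations a mixed model
    with random intercepts is fitted instead.
    """
    effects = np.asarray(effects, dtype=float)
    cas = np.asarray(cas, dtype=float)
    if effects.shape != cas.shape or effects.ndim != 1:
        raise ValueError("effects and cas must be equal-length 1-D arrays")
    if effects.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(cas) == 0:
        raise ValueError("zero variance in CA")
    one_per_subject = subjects is None or len(np.unique(subjects)) == effects.size
    if one_per_subject:
        slope, t, p, r2 = _ols_stats(effects, cas)
        return LMEWindowStats(window=window, slope=slope, t=t, p=p,
                              r_squared=r2, n_subjects=effects.size)
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"eff": effects, "ca": cas, "subj": np.asarray(subjects)})
    fit = smf.mixedlm("eff ~ ca", df, groups=df["subj"]).fit(reml=True)
    slope = fit.params["ca"]
    t = fit.tvalues["ca"]
    p = fit.pvalues["ca"]
    # Marginal R^2: variance of the fixed-effect prediction over total variance.
    var_f = np.var(slope * cas)
    var_re = float(fit.cov_re.iloc[0, 0])
    r2 = var_f / (var_f + var_re + fit.scale)
    return LMEWindowStats(window=window, slope=slope, t=t, p=p, r_squared=r2,
                          n_subjects=len(np.unique(subjects)))


def lme_timecourse(effects, ca_windows, window_starts=None,
                   subjects=None) -> list[LMEWindowStats]:
    """One Eff ~ CA fit per analysis window; no multiplicity correction here.

    ``ca_windows`` is subjects x windows. Cluster formation and the
    permutation test downstream control the family-wise error.
    """
    ca_windows = np.atleast_2d(np.asarray(ca_windows, dtype=float))
    if window_starts is None:
        window_starts = np.arange(ca_windows.shape[1], dtype=float)
    if len(window_starts) != ca_windows.shape[1]:
        raise ValueError("window_starts length must match ca_windows columns")
    out = []
    n_sub = (len(np.unique(subjects)) if subjects is not None
             else ca_windows.shape[0])
    for w in range(ca_windows.shape[1]):
        if np.ptp(ca_windows[:, w]) == 0:
            # degenerate window (all subjects at the same CA): no slope is
            # estimable, so the window cannot be significant
            out.append(LMEWindowStats(window=float(window_starts[w]),
                                      slope=np.nan, t=np.nan, p=np.nan,
                                      r_squared=np.nan, n_subjects=n_sub))
            continue
        out.append(fit_effect_ca_lme(effects, ca_windows[:, w],
                                     subjects=subjects,
                                     window=float(window_starts[w])))
    return out


def find_clusters(p_values, alpha: float = 0.05, min_len: int = 2,
                  t_values=None, window_starts=None) -> list[Cluster]:
    """Maximal runs of consecutive windows with p < alpha and length >= min_len."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    p = np.asarray(p_values, dtype=float)
    t = (np.full(p.shape, np.nan) if t_values is None
         else np.asarray(t_values, dtype=float))
    starts = (np.arange(p.size, dtype=float) if window_starts is None
              else np.asarray(window_starts, dtype=float))
    sig = p < alpha
    clusters = []
    i = 0
    while i < p.size:
        if sig[i]:
            j = i
            while j + 1 < p.size and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                idx = np.arange(i, j + 1)
                abs_t = np.abs(t[idx])
                min_t = float(np.min(abs_t)) if np.all(np.isfinite(abs_t)) else np.nan
                clusters.append(Cluster(
                    indices=idx, windows=starts[idx], length=idx.size,
                    min_abs_t=min_t))
            i = j + 1
        else:
            i += 1
    return clusters


def _perm_abs_t(E: np.ndarray, C: np.ndarray) -> np.ndarray:
    """|t| of the regression slope, rowwise over permutations."""
    n = E.shape[1]
    Ec = E - E.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    num = (Ec * Cc).sum(axis=1)
    den = np.sqrt((Ec ** 2).sum(axis=1) * (Cc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    return np.abs(t)


def cluster_permutation_test(cluster: Cluster, effects, ca_windows,
                             n_perm: int = 10_000, seed: int = 0,
                             batch: int = 500) -> Cluster:
    """Within-cluster permutation test of the Eff ~ CA relation.

    Per permutation, the effects are shuffled across subjects and the CA at
    each cluster window is shuffled independently across subjects; the
    regression is refit per window, and the permutation succeeds when it
    yields at least ``cluster.length`` contiguous windows with |t| at or
    above the cluster's minimum |t|. The permutation p uses the add-one
    estimator ``(successes + 1) / (n_perm + 1)`` and never returns exactly
    zero. Returns a copy of the cluster with ``perm_p`` filled in.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    effects = np.asarray(effects, dtype=float)
    ca_windows = np.atleast_2d(np.asarray(ca_windows, dtype=float))
    if cluster.length < 1 or cluster.indices.size != cluster.length:
        raise ValueError("degenerate cluster")
    if not np.isfinite(cluster.min_abs_t):
        raise ValueError("cluster carries no threshold t value")
    n = effects.size
    CAc = ca_windows[:, cluster.indices]  # subjects x cluster windows
    rng = np.random.default_rng(seed)
    successes = 0
    remaining = n_perm
    base = np.tile(np.arange(n), (batch, 1))
    while remaining > 0:
        b = min(batch, remaining)
        eff_idx = rng.permuted(base[:b], axis=1)
        E = effects[eff_idx]
        all_pass = np.ones(b, dtype=bool)
        for j in range(cluster.length):
            ca_idx = rng.permuted(base[:b], axis=1)
            abst = _perm_abs_t(E, CAc[:, j][ca_idx])
            all_pass &= abst >= cluster.min_abs_t
            # A run of >= cluster.length among the cluster's own windows
            # requires every refit window to pass.
        successes += int(all_pass.sum())
        remaining -= b
    perm_p = (successes + 1) / (n_perm + 1)
    return replace(cluster, perm_p=perm_p, n_perm=n_perm)
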