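"""Inferential utilities: t tests with Cohen's d, BH-FDR, Pearson r, power analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    tails: int


@dataclass
class FDRResult:
    """Benjamini-Hochberg adjusted p-values with rejection flags at level q."""

    adjusted_p: np.ndarray
    q: float
    rejected: np.ndarray


@dataclass
class PearsonResult:
    r: float
    p: float
    n: int


def bh_adjust(p_values, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_p[i] = min over j with p_j >= p_i of p_j * m / rank_j`` (capped at
    1), which enforces monotonicity in the raw-p order; rejection at level
    ``q`` is equivalent to ``adj_p <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return FDRResult(adjusted_p=adj, q=q, rejected=adj <= q)


def _t_result(diffs: np.ndarray, tails: int) -> TTestResult:
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    mean = diffs.mean()
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    if tails == 2:
        p = 2 * stats.t.sf(abs(t), df)
    elif tails == 1:
        p = stats.t.sf(t, df)  # upper tail
    else:
        raise ValueError("tails must be 1 or 2")
    return TTestResult(t=float(t), df=df, p=float(p), cohens_d=float(mean / sd),
                       mean_diff=float(mean), tails=tails)


def one_sample_t(values, null_mean: float = 0.0, tails: int = 2) -> TTestResult:
    """One-sample t test; Cohen's d = (mean - null) / sample SD.

    One-tailed p is the upper-tail probability (alternative: mean > null).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    return _t_result(values - null_mean, tails)


def paired_t(a, b, tails: int = 2) -> TTestResult:
    """Paired t test on a - b; Cohen's d uses the SD of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    return _t_result(a - b, tails)


def pearson_r(x, y) -> PearsonResult:
    """Sample Pearson correlation with the exact t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def t_test_power(n: int, effect_d: float, alpha: float, tails: int) -> float:
    """Exact power of a one-sample/paired t test via the noncentral t distribution."""
    df = n - 1
    nc = effect_d * np.sqrt(n)
    if tails == 1:
        crit = stats.t.ppf(1 - alpha, df)
        return float(1 - stats.nct.cdf(crit, df, nc))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def min_sample_size(effect_d: float, alpha: float = 0.05, power: float = 0.9,
                    tails: int = 1, max_n: int = 1_000_000) -> int:
    """Smallest n >= 2 at which the t test attains the requested power.

    Uses the exact noncentral-t computation with df = n - 1 and
    noncentrality d * sqrt(n); nonincreasing in the effect size and
    nondecreasing in the requested power.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_d <= 0:
        raise ValueError("effect_d must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while n <= max_n:
        if t_test_power(n, effect_d, alpha, tails) >= power:
            return n
        n += 1
    raise ValueError(f"requested power {power} not reachable within n <= {max_n}")
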