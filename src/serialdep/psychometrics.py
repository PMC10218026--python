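"""Psychometric fitting and behavioral serial-dependence measures.

The core model is a lapse-corrected ("finger error") cumulative Gaussian
for two-alternative forced-choice data,

    psi(x) = lambda/2 + (1 - lambda) * Phi((x - mu) / sigma),

fitted by binomial maximum likelihood with the lapse rate fixed (5% by
default). The PSE is the Gaussian median mu, the JND the probe distance
between the 50% and 75% points of the lapse-corrected curve, and the Weber
fraction JND/PSE. The serial-dependence index compares PSEs obtained under
low vs high inducer magnitudes, and the trial-level logistic regression
quantifies how each inducer dimension shifts the single-trial response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from serialdep.params import DIMENSIONS, EXP1_INDUCER_LEVELS, PROBE_LEVELS, REFERENCE


@dataclass
class PsychometricFit:
    """Lapse-corrected cumulative Gaussian MLE with derived PSE / JND / WF."""

    mu: float
    sigma: float
    lapse: float
    jnd: float
    wf: float
    loglik: float
    converged: bool
    boundary: bool
    n_trials: int

    @property
    def pse(self) -> float:
        """Point of subjective equality: the fitted Gaussian median."""
        return self.mu


@dataclass
class SerialDependenceEffect:
    """Normalized PSE difference between high- and low-inducer conditions, in %."""

    eff: float
    pse_low: float
    pse_high: float
    dimension: str
    task: str


@dataclass
class RegressionBetas:
    """Trial-level binomial-logit coefficients on probe and inducer magnitude ratios.

    Positive inducer coefficients indicate an attractive effect (higher
    inducer magnitude raises the probability of judging the reference as
    greater than the probe).
    """

    beta: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    converged: bool
    n_trials: int


def _neg_loglik(mu, sigma, levels, k, n, lapse):
    psi = lapse / 2.0 + (1.0 - lapse) * ndtr((levels - mu) / sigma)
    psi = np.clip(psi, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi))


def fit_psychometric(levels, k_chose_probe, n_total, lapse: float = 0.05) -> PsychometricFit:
    """Binomial MLE of the lapse-corrected cumulative Gaussian.

    Parameters
    ----------
    levels, k_chose_probe, n_total
        Probe magnitudes, counts of "probe greater" choices, and trials per
        level.
    lapse
        Fixed finger-error rate, split equally between floor and ceiling.

    A coarse grid over (mu, sigma) seeds a Nelder-Mead refinement; data with
    responses pinned at 0 or 1 across all levels return a non-converged fit
    with a boundary estimate rather than a silent success.
    """
    levels = np.asarray(levels, dtype=float)
    k = np.asarray(k_chose_probe, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need at least 3 distinct probe levels")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if not 0.0 <= lapse < 1.0:
        raise ValueError("lapse must lie in [0, 1)")
    n_trials = int(n.sum())

    if np.all(k == 0) or np.all(k == n):
        mu = levels.max() if np.all(k == 0) else levels.min()
        return PsychometricFit(mu=mu, sigma=np.nan, lapse=lapse, jnd=np.nan,
                               wf=np.nan, loglik=np.nan, converged=False,
                               boundary=True, n_trials=n_trials)

    span = levels.max() - levels.min()
    mu_grid = np.linspace(levels.min() - 0.5 * span, levels.max() + 0.5 * span, 61)
    sg_grid = np.geomspace(span / 50.0, span * 3.0, 41)
    nll = np.array([[_neg_loglik(m, s, levels, k, n, lapse) for s in sg_grid]
                    for m in mu_grid])
    i, j = np.unravel_index(np.argmin(nll), nll.shape)

    def obj(theta):
        return _neg_loglik(theta[0], np.exp(theta[1]), levels, k, n, lapse)

    res = minimize(obj, x0=[mu_grid[i], np.log(sg_grid[j])], method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    boundary = not (levels.min() <= mu <= levels.max())
    jnd = jnd_from_params(sigma, lapse)
    return PsychometricFit(mu=mu, sigma=sigma, lapse=lapse, jnd=jnd,
                           wf=jnd / mu, loglik=-res.fun,
                           converged=bool(res.success) and not boundary,
                           boundary=boundary, n_trials=n_trials)


def jnd_from_params(sigma: float, lapse: float) -> float:
    """JND on the lapse-corrected curve: sigma * z* with Phi(z*) = (0.75 - lapse/2)/(1 - lapse)."""
    return sigma * ndtri((0.75 - lapse / 2.0) / (1.0 - lapse))


def jnd_from_fit(fit: PsychometricFit) -> float:
    """Probe distance between the 50% and 75% points of the fitted curve."""
    if not fit.converged:
        raise ValueError("cannot derive a JND from a non-converged fit")
    return jnd_from_params(fit.sigma, fit.lapse)


def serial_dependence_index(pse_low: float, pse_high: float) -> float:
    """Serial-dependence effect: ``(PSE_high - PSE_low) / PSE_low * 100``.

    Positive values are attractive (higher inducer magnitude raises the
    perceived reference magnitude).
    """
    if pse_low <= 0:
        raise ValueError("pse_low must be positive")
    return (pse_high - pse_low) / pse_low * 100.0


def trial_regression(table: pd.DataFrame) -> RegressionBetas:
    """Binomial-logit regression of single-trial responses on magnitude ratios.

    The response is recoded so 1 = "reference greater"; predictors are the
    probe magnitude and the three inducer magnitudes, each expressed as the
    ratio to the corresponding reference constant (16 dots / 200 ms / 6 px).
    A positive inducer coefficient is therefore attractive.
    """
    task = table["task"].iloc[0]
    if task not in PROBE_LEVELS:
        raise ValueError("trial_regression requires an active-task (probe) design")
    resp = table["response"].to_numpy(dtype=float)
    keep = np.isfinite(resp)
    if not keep.any():
        raise ValueError("all responses are missing")
    sub = table.loc[keep]
    y = 1.0 - sub["response"].to_numpy(dtype=float)  # 1 = "reference greater"
    X = pd.DataFrame({
        "probe": sub["probe"].to_numpy() / REFERENCE[task],
        "numerosity": sub["inducer_numerosity"].to_numpy() / REFERENCE["numerosity"],
        "duration": sub["inducer_duration"].to_numpy() / REFERENCE["duration"],
        "size": sub["inducer_size"].to_numpy() / REFERENCE["size"],
    })
    X = sm.add_constant(X)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            converged = bool(fit.converged)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=25)
            converged = False
    return RegressionBetas(
        beta=dict(fit.params), se=dict(fit.bse), p=dict(fit.pvalues),
        converged=converged, n_trials=int(keep.sum()))


def effects_by_inducer(table: pd.DataFrame, dimension: str, lapse: float = 0.05,
                       ) -> tuple[PsychometricFit, PsychometricFit, SerialDependenceEffect]:
    """Split trials by the low/high level of one inducer dimension and fit each.

    The other inducer dimensions are marginalized (they cancel in a balanced
    factorial). Returns the low- and high-split fits plus the effect index.
    Trials with missing responses are excluded.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown inducer dimension {dimension!r}")
    task = table["task"].iloc[0]
    if task not in PROBE_LEVELS:
        raise ValueError("effects_by_inducer requires an active-task design")
    low, high = EXP1_INDUCER_LEVELS[dimension]
    fits = {}
    for name, level in (("low", low), ("high", high)):
        sub = table[(table[f"inducer_{dimension}"] == level)
                    & np.isfinite(table["response"].to_numpy(dtype=float))]
        grp = sub.groupby("probe")["response"]
        levels = grp.count().index.to_numpy(dtype=float)
        if levels.size < 3:
            raise ValueError(f"fewer than 3 probe levels in the {name} split")
        fits[name] = fit_psychometric(levels, grp.sum().to_numpy(),
                                      grp.count().to_numpy(), lapse=lapse)
    eff = SerialDependenceEffect(
        eff=serial_dependence_index(fits["low"].pse, fits["high"].pse),
        pse_low=fits["low"].pse, pse_high=fits["high"].pse,
        dimension=dimension, task=task)
    return fits["low"], fits["high"], eff
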