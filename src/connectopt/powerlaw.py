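"""Discrete power-law fitting and goodness-of-fit testing for degree samples.

Implements the maximum-likelihood / Kolmogorov-Smirnov procedure for the
discrete model  p(x) = x^(-gamma) / zeta(gamma, x_min),  x = x_min, x_min+1, ...
The lower cutoff x_min is chosen by minimizing the KS distance between the
tail of the data and the fitted model; the plausibility p-value is the
fraction of semi-parametric surrogate samples (empirical below x_min, model
above) whose own best-fit KS distance is at least as large as the data's.
A small p rules the power law out; a large p means the deviation is
compatible with sampling fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = ["PowerlawFit", "PowerlawFitError", "fit_discrete_powerlaw",
           "powerlaw_test", "sample_discrete_powerlaw"]


class PowerlawFitError(ValueError):
    """Raised when no valid power-law tail can be fitted."""


@dataclass
class PowerlawFit:
    """MLE exponent, cutoff, KS distance and surrogate p-value."""

    gamma: float
    x_min: int
    D: float                      # KS distance of data vs fitted model
    p: float | None               # None when surrogates were not run
    n_tail: int
    surrogate_reps: int = 0


GAMMA_MAX = 6.0
"""Upper bound of the exponent search.

Empirical degree-distribution exponents sit well inside (1, 6); beyond that a
discrete power law over the narrow support of a real tail is indistinguishable
from exponential decay, so admitting steeper exponents only lets the model
mimic non-power-law tails and destroys the test's power.
"""


def _mle_gamma(tail: np.ndarray, x_min: int) -> float:
    """Maximize the discrete log-likelihood over gamma in (1, GAMMA_MAX]."""
    s_logx = np.log(tail).sum()
    n = len(tail)

    def nll(g):
        return g * s_logx + n * np.log(zeta(g, x_min))

    res = minimize_scalar(nll, bounds=(1.0001, GAMMA_MAX), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def _ks_distance(tail: np.ndarray, gamma: float, x_min: int) -> float:
    xs = np.unique(tail)
    n = len(tail)
    ecdf = np.searchsorted(np.sort(tail), xs, side="right") / n
    model_cdf = 1.0 - zeta(gamma, xs + 1) / zeta(gamma, x_min)
    return float(np.abs(ecdf - model_cdf).max())


def fit_discrete_powerlaw(data, x_min: int | None = None,
                          min_tail: int = 10) -> PowerlawFit:
    """Fit the discrete power law, selecting x_min by KS minimization.

    Candidate cutoffs are the unique data values whose tail still holds at
    least *min_tail* points; for each, gamma is fitted by MLE and the KS
    distance evaluated; the cutoff with the smallest KS distance wins.
    """
    data = np.asarray(data)
    data = data[data >= 1].astype(np.int64)
    if len(data) < min_tail:
        raise PowerlawFitError(f"need at least {min_tail} positive values, "
                               f"got {len(data)}")
    if x_min is not None:
        cands = [int(x_min)]
    else:
        cands = [int(v) for v in np.unique(data)
                 if (data >= v).sum() >= min_tail]
        if not cands:
            raise PowerlawFitError("no candidate x_min leaves a usable tail")
    best = None
    for xm in cands:
        tail = data[data >= xm]
        if len(tail) < min_tail or np.all(tail == tail[0]):
            continue
        g = _mle_gamma(tail, xm)
        d = _ks_distance(tail, g, xm)
        if best is None or d < best.D:
            best = PowerlawFit(gamma=g, x_min=xm, D=d, p=None,
                               n_tail=len(tail))
    if best is None:
        raise PowerlawFitError("degenerate sample: no non-constant tail with "
                               f">= {min_tail} points")
    return best


def sample_discrete_powerlaw(gamma: float, x_min: int, size: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF sampling via the Hurwitz-zeta tail function."""
    u = rng.random(size)
    # smallest x >= x_min with  zeta(gamma, x+1) <= (1-u) * zeta(gamma, x_min)
    target = (1.0 - u) * zeta(gamma, x_min)
    lo = np.full(size, x_min, dtype=np.int64)
    hi = lo.copy()
    while True:
        bad = zeta(gamma, hi + 1) > target
        if not bad.any():
            break
        hi[bad] = hi[bad] * 2 + 1
    while np.any(lo < hi):
        mid = (lo + hi) // 2
        ok = zeta(gamma, mid + 1) <= target
        hi = np.where(ok & (lo < hi), mid, hi)
        lo = np.where(~ok & (lo < hi), mid + 1, lo)
    return lo


def powerlaw_test(degrees, surrogate_reps: int = 1000, seed: int = 0,
                  x_min: int | None = None, min_tail: int = 10) -> PowerlawFit:
    """Power-law plausibility test for a degree sample.

    Fits the model to the data, then compares its KS distance with those of
    *surrogate_reps* semi-parametric surrogates, each refitted from scratch
    (cutoff scan included).  ``p`` is the fraction of surrogates whose KS
    distance is >= the data's.
    """
    if surrogate_reps < 1:
        raise ValueError("surrogate_reps must be >= 1")
    data = np.asarray(degrees)
    data = data[data >= 1].astype(np.int64)
    fit = fit_discrete_powerlaw(data, x_min=x_min, min_tail=min_tail)
    rng = np.random.default_rng(seed)
    n = len(data)
    below = data[data < fit.x_min]
    n_tail = fit.n_tail
    exceed = 0
    for _ in range(surrogate_reps):
        take_tail = rng.random(n) < n_tail / n
        k_tail = int(take_tail.sum())
        parts = []
        if k_tail:
            parts.append(sample_discrete_powerlaw(fit.gamma, fit.x_min,
                                                  k_tail, rng))
        if n - k_tail:
            if len(below) == 0:
                parts.append(sample_discrete_powerlaw(fit.gamma, fit.x_min,
                                                      n - k_tail, rng))
            else:
                parts.append(rng.choice(below, size=n - k_tail, replace=True))
        sur = np.concatenate(parts)
        try:
            sfit = fit_discrete_powerlaw(sur, x_min=x_min, min_tail=min_tail)
        except PowerlawFitError:
            continue
        if sfit.D >= fit.D:
            exceed += 1
    return PowerlawFit(gamma=fit.gamma, x_min=fit.x_min, D=fit.D,
                       p=exceed / surrogate_reps, n_tail=fit.n_tail,
                       surrogate_reps=surrogate_reps)
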