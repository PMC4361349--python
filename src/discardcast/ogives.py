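"""Logistic size-selectivity ogives for capture and retention.

Both the capture process (what the commercial gear takes, relative to the
survey's size perception) and the on-board retention process (what the crew
keeps for landing) are described by a two-parameter logistic curve: the
length at 50% selection (L50) and the selection interval (the distance in cm
between the 25% and 75% selection lengths).  In linearised form

    logit(s(l)) = ln(9) / interval * (l - L50)

so that s(L50) = 0.5 and s(L50 + interval) = 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "SelectivityOgive",
    "ogive",
    "fit_retention",
    "crude_retention",
    "estimate_h",
    "retention_from_mls",
]

LN9 = np.log(9.0)


@dataclass(frozen=True)
class SelectivityOgive:
    """Two-parameter logistic selection curve.

    Parameters
    ----------
    l50 : float
        Length (cm) at which selection probability is exactly 0.5.
    interval : float
        Selection interval (cm): distance between the 25% and 75%
        selection lengths.  Must be strictly positive.
    l50_se, interval_se : float, optional
        Standard errors when the ogive was estimated from data.
    """

    l50: float
    interval: float
    l50_se: float | None = None
    interval_se: float | None = None

    def __post_init__(self) -> None:
        if not self.interval > 0:
            raise ValueError(f"selection interval must be > 0, got {self.interval}")

    def __call__(self, length):
        return ogive(length, self)


def ogive(length, params: SelectivityOgive):
    """Selection probability at *length* (cm); vectorised over length."""
    length = np.asarray(length, dtype=float)
    return expit(LN9 / params.interval * (length - params.l50))


def _binom_nll(theta, lengths, k, n):
    l50, log_int = theta
    p = expit(LN9 / np.exp(log_int) * (lengths - l50))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def fit_retention(lengths, proportion_landed, weights) -> SelectivityOgive:
    """Fit a retention ogive to observed proportions landed-at-length.

    Maximum-likelihood binomial fit of the logistic ogive: at each length
    class, ``weights`` fish were observed of which a fraction
    ``proportion_landed`` was retained for landing.  Proportions of exactly
    0 or 1 are handled by the likelihood directly.

    Returns a :class:`SelectivityOgive` with standard errors from the
    inverse observed information.  If the data are completely separated
    (no finite maximum), falls back to :func:`crude_retention` on the
    overlap-free limits with a warning.
    """
    lengths = np.asarray(lengths, dtype=float)
    prop = np.asarray(proportion_landed, dtype=float)
    n = np.asarray(weights, dtype=float)
    if lengths.shape != prop.shape or lengths.shape != n.shape:
        raise ValueError("lengths, proportions and weights must have equal length")
    if lengths.size < 4:
        raise ValueError("need at least 4 length classes to fit a retention ogive")
    if np.any((prop < 0) | (prop > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if not (np.any(prop > 0) and np.any(prop < 1)):
        raise ValueError("proportions are all 0 or all 1; no information on the ogive")

    k = prop * n
    # crude start: midpoint of the interval where proportions cross 0.5
    order = np.argsort(lengths)
    start = np.array([np.interp(0.5, prop[order], lengths[order]), np.log(6.0)])
    res = minimize(_binom_nll, start, args=(lengths, k, n), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    l50, log_int = res.x

    separated = _is_separated(lengths, prop)
    if separated and np.exp(log_int) < 1e-3:
        warnings.warn(
            "complete separation in retention data; falling back to the crude "
            "minimum-landed / maximum-discarded rule", stacklevel=2)
        min_landed = lengths[prop > 0.5].min()
        max_discarded = lengths[prop < 0.5].max()
        return crude_retention(min_landed, max_discarded)

    se_l50 = se_int = None
    hess = _numerical_hessian(res.x, lengths, k, n)
    try:
        cov = np.linalg.inv(hess)
        if np.all(np.diag(cov) > 0):
            se_l50 = float(np.sqrt(cov[0, 0]))
            # delta method from log-interval to interval
            se_int = float(np.sqrt(cov[1, 1]) * np.exp(log_int))
    except np.linalg.LinAlgError:
        pass
    return SelectivityOgive(float(l50), float(np.exp(log_int)),
                            l50_se=se_l50, interval_se=se_int)


def _is_separated(lengths, prop) -> bool:
    """True when every length below some threshold has p=0 and above p=1."""
    order = np.argsort(lengths)
    p = prop[order]
    informative = (p > 0) & (p < 1)
    return not np.any(informative)


def _numerical_hessian(theta, lengths, k, n, eps=1e-4):
    m = len(theta)
    hess = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            ei = np.eye(m)[i] * eps
            ej = np.eye(m)[j] * eps
            hess[i, j] = (
                _binom_nll(theta + ei + ej, lengths, k, n)
                - _binom_nll(theta + ei - ej, lengths, k, n)
                - _binom_nll(theta - ei + ej, lengths, k, n)
                + _binom_nll(theta - ei - ej, lengths, k, n)
            ) / (4 * eps * eps)
    return hess


def crude_retention(min_landed_length: float, max_discarded_length: float) -> SelectivityOgive:
    """Retention ogive from the overlap limits of landed and discarded fish.

    The retention interval is the difference between the minimum length of
    landed fish and the maximum length of those discarded, and the 50%
    retention length sits mid-way between the two.
    """
    if min_landed_length <= 0 or max_discarded_length <= 0:
        raise ValueError("both limit lengths must be positive")
    ri = abs(max_discarded_length - min_landed_length)
    if ri == 0:
        raise ValueError("landed and discarded limits coincide; interval must be > 0")
    return SelectivityOgive((max_discarded_length + min_landed_length) / 2.0, ri)


def estimate_h(rl50_by_species, mls_by_species) -> float:
    """Ratio of summed 50% retention lengths to summed minimum landing sizes.

    h = sum_k RL50_k / sum_k MLS_k — a ratio of sums, not a mean of ratios.
    Used to set the retention length of landings-only species as h * MLS.
    """
    rl50 = np.asarray(rl50_by_species, dtype=float)
    mls = np.asarray(mls_by_species, dtype=float)
    if rl50.shape != mls.shape:
        raise ValueError("RL50 and MLS lists must have equal length")
    if np.any(rl50 <= 0) or np.any(mls <= 0):
        raise ValueError("RL50 and MLS values must be positive")
    denom = mls.sum()
    if denom == 0:
        raise ValueError("sum of MLS values is zero")
    return float(rl50.sum() / denom)


def retention_from_mls(mls: float, h: float) -> float:
    """50% retention length (cm) proxied from a minimum landing size."""
    if mls <= 0:
        raise ValueError("MLS must be positive")
    if h <= 0:
        raise ValueError("h must be positive")
    return h * mls
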