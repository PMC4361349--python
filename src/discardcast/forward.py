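"""Deterministic forward model: latent states + length composition -> catch,
discards, landings, and the size/quantity partition of discards.

The central relations, for year t with survey index u_t, catch ratio Q_t,
capture selectivity s'_i, retention selectivity r_i and length-composition
proportions pi_{i,t}:

    C_t = u_t Q_t * sum_i s'_i pi_{i,t}
    D_t = u_t Q_t * ( sum_i s'_i pi_{i,t} + (q_t - 1) sum_i r_i s'_i pi_{i,t} )
    L_t = C_t - D_t

q_t in [0, 1] is the annual fraction of catch discarded in bulk regardless
of size ("quantity-related" discarding).  Discards partition into a
quantity-selected component q_t*C_t and a size-selected remainder.
Observations of the index, landings and discards are lognormal around the
latent truths; the likelihood convention here is the normal density of the
*log*-observation (so a zero residual with sd 1 contributes -0.5*ln(2*pi)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ogives import SelectivityOgive, ogive

__all__ = [
    "ForwardOutputs",
    "selection_sums",
    "predicted_catch",
    "predicted_discards",
    "forward_series",
    "partition_discards",
    "log_likelihood",
    "weighted_logQ",
    "discards_from_proportion",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ForwardOutputs:
    """Annual forward-model outputs (tonnes, except the proportion p)."""

    catch: np.ndarray
    discards: np.ndarray
    landings: np.ndarray
    quantity_component: np.ndarray
    size_component: np.ndarray
    p: np.ndarray  # proportion of catch discarded, D/C


def selection_sums(pi, lengths, capture: SelectivityOgive, retention: SelectivityOgive):
    """Composition-weighted selection sums (S_t, R_t).

    S_t = sum_i s'_i pi_{i,t} and R_t = sum_i r_i s'_i pi_{i,t}; pi may be a
    single year (1-d over classes) or a years x classes matrix.
    """
    pi = np.asarray(pi, dtype=float)
    s = ogive(lengths, capture)
    r = ogive(lengths, retention)
    return pi @ s, pi @ (r * s)


def predicted_catch(u_t, q_ratio, capture: SelectivityOgive, pi_t, lengths) -> float:
    """Predicted total catch C_t = u_t * Q_t * sum_i s'_i pi_{i,t}."""
    pi_t = np.asarray(pi_t, dtype=float)
    s = ogive(lengths, capture)
    return float(u_t) * float(q_ratio) * float(pi_t @ s)


def predicted_discards(u_t, q_ratio, capture: SelectivityOgive,
                       retention: SelectivityOgive, pi_t, lengths, q_t) -> float:
    """Predicted discards D_t = u_t Q_t (S_t + (q_t - 1) R_t)."""
    if not 0.0 <= q_t <= 1.0:
        raise ValueError(f"q_t must lie in [0, 1], got {q_t}")
    s_sum, r_sum = selection_sums(np.asarray(pi_t, dtype=float), lengths, capture, retention)
    return float(u_t) * float(q_ratio) * float(s_sum + (q_t - 1.0) * r_sum)


def forward_series(u, q_ratio, capture: SelectivityOgive, retention: SelectivityOgive,
                   pi, lengths, q) -> ForwardOutputs:
    """Vectorised forward model over a span of years.

    Parameters are per-year arrays (u, q_ratio, q) and a years x classes
    proportion matrix pi.  Returns all derived annual quantities.
    """
    u = np.asarray(u, dtype=float)
    q_ratio = np.asarray(q_ratio, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(u <= 0) or np.any(q_ratio <= 0):
        raise ValueError("u_t and Q_t must be strictly positive")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q_t must lie in [0, 1]")
    s_sum, r_sum = selection_sums(pi, lengths, capture, retention)
    catch = u * q_ratio * s_sum
    discards = u * q_ratio * (s_sum + (q - 1.0) * r_sum)
    landings = catch - discards
    quantity = q * catch
    size = discards - quantity
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(catch > 0, discards / catch, np.nan)
    return ForwardOutputs(catch, discards, landings, quantity, size, p)


def partition_discards(catch, discards, q_t):
    """Split discards into (quantity-selected, size-selected) tonnes."""
    catch = np.asarray(catch, dtype=float)
    discards = np.asarray(discards, dtype=float)
    q_t = np.asarray(q_t, dtype=float)
    quantity = q_t * catch
    size = discards - quantity
    tol = 1e-9 * np.maximum(1.0, np.abs(catch))
    if np.any(discards > catch + tol) or np.any(quantity > discards + tol):
        raise ValueError("requires q_t * C_t <= D_t <= C_t")
    return quantity, size


def _lognormal_terms(observed, predicted, sigma):
    """Normal log-density of log(observed) around log(predicted); NaN-safe."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    mask = ~np.isnan(observed)
    if np.any(observed[mask] <= 0):
        raise ValueError("observed values must be positive on the log scale")
    resid = np.log(observed[mask]) - np.log(predicted[mask])
    return -0.5 * _LOG2PI - np.log(sigma) - 0.5 * (resid / sigma) ** 2


def log_likelihood(observed_index, observed_landings, observed_discards,
                   predicted_index, predicted_landings, predicted_discards_,
                   sigma_index, sigma_landings, sigma_discards) -> float:
    """Joint log-likelihood of the index, landings and discard series.

    Each observed series is lognormal about its latent prediction; the
    density is that of the log-observation.  Missing observations (NaN, or
    a series passed as None) are skipped.
    """
    for s in (sigma_index, sigma_landings, sigma_discards):
        if s is not None and s <= 0:
            raise ValueError("observation sds must be positive")
    total = 0.0
    pairs = [
        (observed_index, predicted_index, sigma_index),
        (observed_landings, predicted_landings, sigma_landings),
        (observed_discards, predicted_discards_, sigma_discards),
    ]
    for obs, pred, sigma in pairs:
        if obs is None:
            continue
        total += float(np.sum(_lognormal_terms(obs, pred, sigma)))
    return total


def weighted_logQ(w, logq_reference):
    """Per-year weighted sum of reference log catch-ratio series.

    log(Q_t) = sum_k w_k log(Q_{k,t}) with w on the unit simplex, so that
    exp of the result is a weighted geometric mean of the reference Q's.
    """
    w = np.asarray(w, dtype=float)
    logq_reference = np.asarray(logq_reference, dtype=float)
    if w.ndim != 1 or logq_reference.ndim != 2 or w.size != logq_reference.shape[0]:
        raise ValueError("w must be 1-d with one entry per reference series (rows)")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be non-negative and sum to 1 within 1e-8")
    return w @ logq_reference


def discards_from_proportion(landings, p):
    """Discards implied by landings and a discard proportion: D = p L / (1 - p)."""
    landings = np.asarray(landings, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must lie in [0, 1); the inflation factor diverges at 1")
    out = p * landings / (1.0 - p)
    return float(out) if out.ndim == 0 else out
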