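"""Validation procedures and assemblage-level aggregation.

Covers: leave-discards-out cross-validation of the reduced model against
the reference species; a crude knife-edge estimate of the bulk-discard
fraction q from age compositions; logit-mean comparison of modelled and
observed discard proportions; one-at-a-time sensitivity of discard
estimates to the selectivity parameters; and draw-wise aggregation of
per-species posteriors into assemblage totals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import ReducedDiscardModel

logger = logging.getLogger(__name__)

__all__ = [
    "cross_validate",
    "q_from_age",
    "compare_p",
    "sensitivity",
    "aggregate_assemblage",
    "variance_explained",
]


def cross_validate(reference_obs, full_results, mls, priors=None,
                   value_class: str = "high", draws: int = 1000,
                   warmup: int = 1000, chains: int = 2, seed: int = 0) -> dict:
    """Leave-discards-out cross-validation of the reduced model.

    Each reference species is refitted with the reduced model using its
    landings and index only; the species' own Q series remains one of the
    candidate reference series.  Returns the (species x reference) posterior
    mean weight matrix, the per-species predicted discard summaries, and the
    coverage of the withheld discard observations by the 95% intervals.
    """
    ref_logq = full_results.reference_logq()
    h = full_results.h
    names = full_results.species
    weight_rows, coverage, predicted = [], {}, {}
    for i, obs in enumerate(reference_obs):
        reduced = ReducedDiscardModel(
            obs.without_discards(), ref_logq, mls[obs.species], h,
            priors=priors, value_class=value_class,
            reference_species=names)
        res = reduced.fit(draws=draws, warmup=warmup, chains=chains,
                          seed=seed + i)
        weight_rows.append(res.weights_mean)
        d_sum = res.series_summary("D")
        predicted[obs.species] = d_sum
        if obs.discards is not None:
            ok = np.isfinite(obs.discards)
            inside = ((obs.discards >= d_sum["lo"].to_numpy())
                      & (obs.discards <= d_sum["hi"].to_numpy()))[ok]
            coverage[obs.species] = float(inside.mean())
    weights = pd.DataFrame(np.vstack(weight_rows), index=names, columns=names)
    diag_hits = int(sum(weights.to_numpy()[i].argmax() == i
                        for i in range(len(names))))
    return {"weights": weights, "coverage": coverage, "predicted": predicted,
            "diagonal_hits": diag_hits}


def q_from_age(records: pd.DataFrame, mls: float, lw, increment: float = 1.0) -> pd.Series:
    """Knife-edge estimate of the bulk-discard fraction q per year.

    The threshold body weight is a*(MLS + increment)^b; for each year, q is
    the discarded weight summed over age classes whose mean body weight
    exceeds the threshold, divided by the catch (landings + discards)
    weight over the same classes.  Years with no supra-threshold class
    yield NaN with a log note.

    ``records`` columns: year, age, n_landed_thousands, w_landed_kg,
    n_discarded_thousands, w_discarded_kg.
    """
    threshold_kg = lw.weight_g(mls + increment) / 1000.0
    out = {}
    for year, grp in records.groupby("year"):
        landed_w = grp["n_landed_thousands"] * grp["w_landed_kg"]
        disc_w = grp["n_discarded_thousands"] * grp["w_discarded_kg"]
        supra_l = grp["w_landed_kg"] > threshold_kg
        supra_d = grp["w_discarded_kg"] > threshold_kg
        catch = landed_w[supra_l].sum() + disc_w[supra_d].sum()
        if not (supra_l.any() or supra_d.any()) or catch <= 0:
            logger.warning("year %s: no age class above the %.1f kg threshold",
                           year, threshold_kg)
            out[year] = np.nan
            continue
        out[year] = float(disc_w[supra_d].sum() / catch)
    return pd.Series(out, name="q_hat")


def compare_p(model_p: dict, observed_fragments: pd.DataFrame) -> pd.DataFrame:
    """Logit-mean observed discard proportions vs model means per species.

    ``model_p`` maps species to the model's mean proportion discarded over
    the comparison window (natural scale).  ``observed_fragments`` has
    columns ``species`` and ``p_observed``; entries with p = 1 (fully
    discarded classes) are excluded with a log note, p outside (0, 1)
    rejected.  Species with no fragments are omitted.
    """
    frags = observed_fragments.copy()
    n_dropped = int((frags["p_observed"] >= 1).sum())
    if n_dropped:
        logger.info("excluding %d fragment(s) with p = 1 from the comparison",
                    n_dropped)
        frags = frags[frags["p_observed"] < 1]
    if np.any(frags["p_observed"] <= 0):
        raise ValueError("observed proportions must lie in (0, 1)")
    rows = []
    for sp, grp in frags.groupby("species"):
        if sp not in model_p:
            continue
        obs_mean = float(expit(np.mean(logit(grp["p_observed"]))))
        rows.append({"species": sp, "observed_logit_mean": obs_mean,
                     "model_mean": model_p[sp],
                     "deviation": model_p[sp] - obs_mean,
                     "n_fragments": len(grp)})
    return pd.DataFrame(rows)


def sensitivity(fit_callable, baseline_config: dict, parameter: str,
                delta: float, statistic: str = "D") -> dict:
    """Signed % change in mean total discards under a one-at-a-time perturbation.

    ``fit_callable(config) -> per-draw discard series draws (n, T)`` runs
    the model under a configuration; ``baseline_config`` must fix the seed
    so a zero perturbation reproduces the baseline exactly.  ``parameter``
    names the config entry to scale by (1 + delta), e.g. ``rl50``,
    ``sl50_prior_mean`` or ``q_prior_scale``; ``qmean`` may instead be
    switched by passing it directly in a modified config.
    """
    base_draws = fit_callable(dict(baseline_config))
    cfg = dict(baseline_config)
    if parameter not in cfg:
        raise KeyError(f"unknown sensitivity parameter {parameter!r}")
    cfg[parameter] = cfg[parameter] * (1.0 + delta)
    pert_draws = fit_callable(cfg)
    base_mean = float(np.mean(base_draws))
    pert_mean = float(np.mean(pert_draws))
    change = 100.0 * (pert_mean - base_mean) / base_mean
    return {"parameter": parameter, "delta": delta,
            "baseline_mean": base_mean, "perturbed_mean": pert_mean,
            "percent_change": change, "statistic": statistic}


def aggregate_assemblage(per_species_draws: dict, groups: dict | None = None,
                         years=None) -> dict:
    """Draw-wise assemblage totals from per-species posterior draws.

    ``per_species_draws`` maps species to dicts with at least ``C`` and
    ``D`` draw arrays of shape (n_draws, n_years); totals are computed per
    retained draw and only then summarised, so the credible intervals are
    those of the sums.  Optionally includes the quantity/size split (from
    per-draw ``q``) and per-group shares of total discards.
    """
    names = list(per_species_draws)
    n = min(per_species_draws[s]["C"].shape[0] for s in names)
    C = np.stack([per_species_draws[s]["C"][:n] for s in names])  # (K, n, T)
    D = np.stack([per_species_draws[s]["D"][:n] for s in names])
    total_C = C.sum(axis=0)
    total_D = D.sum(axis=0)
    total_L = total_C - total_D
    overall_p = total_D / total_C
    out = {
        "years": np.asarray(years) if years is not None else None,
        "species": names,
        "total_C": _summ(total_C), "total_D": _summ(total_D),
        "total_L": _summ(total_L), "overall_p": _summ(overall_p),
    }
    if all("q" in per_species_draws[s] for s in names):
        qC = np.stack([per_species_draws[s]["q"][:n] * per_species_draws[s]["C"][:n]
                       for s in names])
        quantity = qC.sum(axis=0)
        size = total_D - quantity
        out["quantity_component"] = _summ(quantity)
        out["size_component"] = _summ(size)
        out["size_share"] = _summ(size / total_D)
    if groups is not None:
        shares = {}
        for g in sorted(set(groups.values())):
            members = [i for i, s in enumerate(names) if groups.get(s) == g]
            if members:
                shares[g] = _summ(D[members].sum(axis=0) / total_D)
        out["group_discard_shares"] = shares
    out["_draws"] = {"total_C": total_C, "total_D": total_D,
                     "overall_p": overall_p}
    return out


def _summ(arr):
    qs = np.quantile(arr, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame({"median": qs[1], "lo": qs[0], "hi": qs[2],
                         "mean": arr.mean(axis=0)})


def variance_explained(model_median, observed) -> float:
    """Coefficient of determination r^2 = 1 - SS_res / SS_tot.

    Residuals are observed minus the model median; SS_tot is about the
    observed mean.  May be negative for a model worse than the observed
    mean.  Pairs with missing values are dropped; needs >= 3 pairs and
    non-zero observed variance.
    """
    m = np.asarray(model_median, dtype=float)
    o = np.asarray(observed, dtype=float)
    ok = np.isfinite(m) & np.isfinite(o)
    m, o = m[ok], o[ok]
    if m.size < 3:
        raise ValueError("need at least 3 paired non-missing values")
    ss_tot = np.sum((o - o.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; r^2 undefined")
    ss_res = np.sum((o - m) ** 2)
    return float(1.0 - ss_res / ss_tot)
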