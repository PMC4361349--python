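"""Synthetic multi-species survey / landings / discards datasets.

The generator reproduces the statistical structure the estimation model
assumes: catch ratios Q_t and latent indices u_t follow multiplicative
random walks; annual bulk-discard fractions q_t are Beta-distributed;
capture 50%-selection lengths are drawn around a common fleet mean with a
species random effect; retention lengths are proportional to the minimum
landing size (RL50 = h * MLS); and observed index, landings and discard
series are the latent truths times lognormal measurement error.

The default scenario mirrors a mixed demersal fishery monitored by a Q1
bottom-trawl survey over 34 years: five "reference" species with observed
discards (minimum landing sizes 35, 30, 27, 27 and 24 cm) plus
landings-only species whose catch ratios are geometric-mean blends of the
reference paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import FisheryObservations
from .forward import forward_series
from .ogives import SelectivityOgive, retention_from_mls
from .survey import LengthComposition

__all__ = [
    "TruthRecord",
    "simulate_random_walk",
    "simulate_length_compositions",
    "simulate_species_observations",
    "simulate_haul_table",
    "reference_scenario",
]

# Scenario defaults: observation sds on the log scale, random-walk process
# sds, and the hierarchical selectivity structure used for data generation.
DEFAULT_SIGMA_INDEX = 0.15
DEFAULT_SIGMA_LANDINGS = 0.10
DEFAULT_SIGMA_DISCARDS = 0.20
DEFAULT_SIGMA_Q = 0.15
DEFAULT_SIGMA_U = 0.10
DEFAULT_SL50_MEAN = 15.25
DEFAULT_SL50_SD = 2.0
DEFAULT_SI = 6.0
DEFAULT_RI = 6.0
DEFAULT_H = 0.874
DEFAULT_Q_BETA = (0.5, 3.0)
REFERENCE_MLS = (35.0, 30.0, 27.0, 27.0, 24.0)  # cod, haddock, whiting, plaice, sole
OTHER_MLS = (25.0, 30.0, 28.0, 27.0, 20.0)      # dab, gurnard, witch, flounder, megrim


@dataclass
class TruthRecord:
    """Generating truth for one synthetic species."""

    species: str
    years: np.ndarray
    q_ratio: np.ndarray            # Q_t, catch ratio (> 0)
    u: np.ndarray                  # latent biomass index (> 0)
    q: np.ndarray                  # bulk-discard fraction, in [0, 1]
    capture: SelectivityOgive
    retention: SelectivityOgive
    sigma_index: float
    sigma_landings: float
    sigma_discards: float
    mls: float
    landings_only: bool = False
    weights: np.ndarray | None = None   # blend weights over reference Q paths
    catch: np.ndarray = field(default=None)     # type: ignore[assignment]
    discards: np.ndarray = field(default=None)  # type: ignore[assignment]
    landings: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for name in ("q_ratio", "u", "q"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.q_ratio <= 0) or np.any(self.u <= 0):
            raise ValueError("Q_t and u_t must be strictly positive")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("q_t must lie in [0, 1]")
        for s in (self.sigma_index, self.sigma_landings, self.sigma_discards):
            if s < 0:
                raise ValueError("observation sds must be non-negative")

    def complete(self, composition: LengthComposition) -> "TruthRecord":
        """Fill in the exact forward-model catch, discard and landing series."""
        out = forward_series(self.u, self.q_ratio, self.capture, self.retention,
                             composition.proportions_filled(), composition.lengths,
                             self.q)
        self.catch, self.discards, self.landings = out.catch, out.discards, out.landings
        return self


def simulate_random_walk(initial: float, sigma: float, n_years: int,
                         seed: int | np.random.Generator) -> np.ndarray:
    """Multiplicative-error random walk x_t = x_{t-1} * exp(e_t), e_t ~ N(0, sigma)."""
    if initial <= 0:
        raise ValueError("initial value must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, sigma, size=n_years - 1) if n_years > 1 else np.empty(0)
    return initial * np.exp(np.concatenate([[0.0], np.cumsum(steps)]))


def simulate_length_compositions(length_grid, mean_length_path, sd_length: float,
                                 total_index_path, n_years: int,
                                 seed: int | np.random.Generator = 0,
                                 species: str = "synthetic",
                                 shape_fn=None) -> LengthComposition:
    """Annual biomass-at-length from a discretised normal length density.

    The per-year shape is a normal density with mean ``mean_length_path[t]``
    and sd ``sd_length``, integrated over 1-cm classes and normalised to sum
    to one, then scaled by ``total_index_path[t]``.  ``shape_fn(lengths,
    year_idx, rng) -> unnormalised densities`` can replace the normal shape.
    """
    grid = np.asarray(length_grid, dtype=float)
    if grid.size < 3:
        raise ValueError("length grid must have at least 3 classes")
    if sd_length <= 0:
        raise ValueError("sd_length must be positive")
    mean_path = np.broadcast_to(np.asarray(mean_length_path, dtype=float), (n_years,))
    total_path = np.broadcast_to(np.asarray(total_index_path, dtype=float), (n_years,))
    if np.any(total_path < 0):
        raise ValueError("total index path must be non-negative")
    rng = np.random.default_rng(seed)
    density = np.empty((n_years, grid.size))
    for t in range(n_years):
        if shape_fn is not None:
            shape = np.asarray(shape_fn(grid, t, rng), dtype=float)
        else:
            # integrate the normal density over [l - 0.5, l + 0.5]
            shape = (norm.cdf(grid + 0.5, mean_path[t], sd_length)
                     - norm.cdf(grid - 0.5, mean_path[t], sd_length))
        s = shape.sum()
        density[t] = total_path[t] * shape / s if s > 0 else 0.0
    years = np.arange(n_years)
    return LengthComposition(species, years, grid, density)


def simulate_species_observations(truth: TruthRecord,
                                  composition: LengthComposition,
                                  seed: int | np.random.Generator) -> FisheryObservations:
    """Noisy observations of one species from its generating truth.

    The true catch/discard/landing series come from the forward model
    exactly; observed series multiply the truths by exp(normal error) with
    the truth's observation sds.  Discards are omitted when the species is
    flagged landings-only.  The returned composition is rescaled so its
    annual totals equal the observed index.
    """
    if truth.years.size != composition.years.size:
        raise ValueError("truth and composition must cover the same years")
    rng = np.random.default_rng(seed)
    truth.complete(composition)
    n = truth.years.size
    index_obs = truth.u * np.exp(rng.normal(0.0, truth.sigma_index, n))
    landings_obs = truth.landings * np.exp(rng.normal(0.0, truth.sigma_landings, n))
    discards_noise = rng.normal(0.0, truth.sigma_discards, n)
    discards_obs = None if truth.landings_only else truth.discards * np.exp(discards_noise)
    pi = composition.proportions_filled()
    obs_comp = LengthComposition(truth.species, truth.years, composition.lengths,
                                 pi * index_obs[:, None])
    return FisheryObservations(truth.species, truth.years, index_obs,
                               landings_obs, discards_obs, obs_comp)


def simulate_haul_table(composition: LengthComposition, density_scale: float,
                        hauls_per_year: int, swept_area_range,
                        seed: int | np.random.Generator, lw=None):
    """Haul-level survey tables with Poisson catch counts.

    Per haul, the count in each length class is Poisson with mean
    (number density) x (swept area).  The number density is
    ``density_scale`` x the year's length proportions, or — when an
    allometric ``lw`` is given — the composition's biomass density
    converted to fish km^-2 cm^-1 (so the survey-processing chain can
    recover the biomass composition exactly in expectation).

    Returns ``(hauls, lengths)`` DataFrames in the two-table CSV dialect.
    """
    import pandas as pd

    if hauls_per_year < 1:
        raise ValueError("need at least one haul per year")
    lo, hi = swept_area_range
    if lo <= 0 or hi < lo:
        raise ValueError("swept areas must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    if lw is not None:
        weights_kg = lw.weight_g(composition.lengths) / 1000.0
        number_density = composition.density / weights_kg[None, :]
    else:
        pi = np.nan_to_num(composition.proportions, nan=0.0)
        number_density = density_scale * pi
    haul_rows, length_rows = [], []
    hid = 0
    for t, year in enumerate(composition.years):
        for _ in range(hauls_per_year):
            hid += 1
            area = rng.uniform(lo, hi)
            haul_rows.append({"haul_id": f"H{hid:05d}", "year": int(year),
                              "region": "IVa", "swept_area_km2": area,
                              "distance_km": np.nan, "wingspread_km": np.nan,
                              "duration_min": 30.0, "depth_m": 80.0})
            counts = rng.poisson(number_density[t] * area)
            for length, c in zip(composition.lengths, counts):
                if c > 0:
                    length_rows.append({"haul_id": f"H{hid:05d}",
                                        "species": composition.species,
                                        "length_cm": float(length), "count": int(c)})
    hauls = pd.DataFrame(haul_rows)
    lengths = pd.DataFrame(length_rows,
                           columns=["haul_id", "species", "length_cm", "count"])
    return hauls, lengths


def _species_truth(name, mls, years, logq1, u1, sl50, rng, sigma_q_rw, sigma_u_rw,
                   q_beta, sigmas, landings_only=False, q_path=None, weights=None):
    n = years.size
    q_ratio = (np.exp(q_path) if q_path is not None else
               simulate_random_walk(np.exp(logq1), sigma_q_rw, n, rng))
    u = simulate_random_walk(u1, sigma_u_rw, n, rng)
    q = rng.beta(q_beta[0], q_beta[1], size=n)
    capture = SelectivityOgive(sl50, DEFAULT_SI)
    retention = SelectivityOgive(retention_from_mls(mls, DEFAULT_H), DEFAULT_RI)
    return TruthRecord(name, years, q_ratio, u, q, capture, retention,
                       sigmas[0], sigmas[1], sigmas[2], mls,
                       landings_only=landings_only, weights=weights)


def reference_scenario(n_reference: int = 5, n_other: int = 3, n_years: int = 34,
                       seed: int = 0, first_year: int = 1978,
                       sigma_index: float = DEFAULT_SIGMA_INDEX,
                       sigma_landings: float = DEFAULT_SIGMA_LANDINGS,
                       sigma_discards: float = DEFAULT_SIGMA_DISCARDS,
                       q_beta=DEFAULT_Q_BETA) -> dict:
    """Full synthetic study: reference species with discards + landings-only species.

    Reference species carry observed discard series; the other species are
    landings-only, with catch-ratio paths that are weighted geometric means
    of the reference paths (Dirichlet-drawn weights, stored in the truth).
    Capture SL50s are drawn around the common fleet mean; retention lengths
    are h x MLS.

    Returns a dict with keys ``reference`` and ``other`` (lists of
    ``(TruthRecord, FisheryObservations)`` tuples), the length grid, and the
    scenario-level constants (``sl50_mean``, ``sl50_sd``, ``h``).
    """
    if n_reference < 2:
        raise ValueError("need at least two reference species")
    rng = np.random.default_rng(seed)
    years = np.arange(first_year, first_year + n_years)
    grid = np.arange(5.0, 71.0)
    sigmas = (sigma_index, sigma_landings, sigma_discards)

    ref_names = ["cod", "haddock", "whiting", "plaice", "sole"]
    ref_mls = list(REFERENCE_MLS)
    while len(ref_names) < n_reference:
        k = len(ref_names)
        ref_names.append(f"reference_{k + 1}")
        ref_mls.append(float(rng.uniform(22, 36)))
    other_names = ["dab", "gurnard", "witch", "flounder", "megrim"]
    other_mls = list(OTHER_MLS)
    while len(other_names) < n_other:
        k = len(other_names)
        other_names.append(f"other_{k + 1}")
        other_mls.append(float(rng.uniform(20, 32)))

    reference, ref_logq = [], []
    for k in range(n_reference):
        sl50 = float(rng.normal(DEFAULT_SL50_MEAN, DEFAULT_SL50_SD))
        logq1 = 4.5 + 2.0 * k / max(n_reference - 1, 1) + rng.normal(0, 0.1)
        u1 = float(np.exp(rng.uniform(5.5, 6.5)))
        truth = _species_truth(ref_names[k], ref_mls[k], years, logq1, u1, sl50,
                               rng, DEFAULT_SIGMA_Q, DEFAULT_SIGMA_U, q_beta, sigmas)
        comp = simulate_length_compositions(
            grid, ref_mls[k] + rng.uniform(-2, 2), 7.0, truth.u, n_years,
            species=ref_names[k])
        obs = simulate_species_observations(truth, comp, rng)
        ref_logq.append(np.log(truth.q_ratio))
        reference.append((truth, obs))
    ref_logq = np.asarray(ref_logq)

    other = []
    for k in range(n_other):
        sl50 = float(rng.normal(DEFAULT_SL50_MEAN, DEFAULT_SL50_SD))
        w = rng.dirichlet(np.ones(n_reference))
        q_path = w @ ref_logq
        u1 = float(np.exp(rng.uniform(5.0, 6.5)))
        truth = _species_truth(other_names[k], other_mls[k], years, 0.0, u1, sl50,
                               rng, DEFAULT_SIGMA_Q, DEFAULT_SIGMA_U, q_beta, sigmas,
                               landings_only=True, q_path=q_path, weights=w)
        comp = simulate_length_compositions(
            grid, other_mls[k] + rng.uniform(-3, 1), 6.0, truth.u, n_years,
            species=other_names[k])
        obs = simulate_species_observations(truth, comp, rng)
        other.append((truth, obs))

    return {
        "reference": reference,
        "other": other,
        "length_grid": grid,
        "years": years,
        "sl50_mean": DEFAULT_SL50_MEAN,
        "sl50_sd": DEFAULT_SL50_SD,
        "h": DEFAULT_H,
        "mls": dict(zip(ref_names[:n_reference] + other_names[:n_other],
                        ref_mls[:n_reference] + other_mls[:n_other])),
    }
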