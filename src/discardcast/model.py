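"""Model and Results objects for Bayesian discard hind-casting.

Two models are exposed, in the statsmodels idiom (construct from data,
``fit()`` returns a results object):

* :class:`DiscardModel` — the *full* model, fitted jointly to the reference
  species for which landings, discards and a survey index are all observed.
  It estimates the catch ratios Q_{k,t}, latent indices u_{k,t}, capture and
  retention ogives (with the capture 50%-lengths pooled through a common
  fleet mean), annual bulk-discard fractions q_{k,t}, and the observation /
  process error sds.

* :class:`ReducedDiscardModel` — the *reduced* model for a single species
  with landings and index only.  Its catch ratio is a Dirichlet-weighted
  geometric mean of the reference species' posterior Q series, and its
  retention length is proxied as h x MLS with h from the full fit.

Both fits run several independent adaptive MCMC chains; results objects
carry the pooled draws, posterior summaries (median and 95% credible
intervals), convergence diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import FisheryObservations
from .mcmc import FullModelSampler, ReducedModelSampler
from .ogives import estimate_h
from .priors import PriorSet, full_model_priors, reduced_model_priors

__all__ = [
    "DiscardModel",
    "ReducedDiscardModel",
    "DiscardResults",
    "ReducedDiscardResults",
    "summarize_posterior",
    "check_convergence",
]

# test-scale defaults; paper-mode configs below reproduce the printed runs
DEFAULT_CHAINS = 4
DEFAULT_WARMUP = 2000
DEFAULT_DRAWS = 2000
PAPER_MODE_FULL = {"chains": 1, "warmup": 15_000, "draws": 35_000}
PAPER_MODE_REDUCED = {"chains": 1, "warmup": 50_000, "draws": 15_000}


def _stack_chains(chain_outputs):
    return {k: np.stack([c[k] for c in chain_outputs]) for k in chain_outputs[0]}


def summarize_posterior(draws: np.ndarray, names=None, axis_labels=None) -> pd.DataFrame:
    """Elementwise median and 95% credible interval of posterior draws.

    ``draws`` has shape (n_draws, ...); at least 100 draws are required.
    Returns a tidy frame with columns ``median``, ``lo`` (2.5%), ``hi``
    (97.5%), whose rows follow the flattened trailing axes.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    qs = np.quantile(draws, [0.025, 0.5, 0.975], axis=0)
    flat = [q.ravel() for q in qs]
    out = pd.DataFrame({"lo": flat[0], "median": flat[1], "hi": flat[2]})
    if names is not None:
        out.index = pd.Index(names)
    return out[["median", "lo", "hi"]]


def check_convergence(draws_by_chain: dict, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter via arviz.

    ``draws_by_chain`` maps parameter names to arrays of shape
    (chain, draw, ...).  Requires at least two chains.  Returns one row per
    scalar element with a ``pass`` flag (R-hat below the threshold).
    """
    import arviz as az

    rows = []
    for name, arr in draws_by_chain.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim < 2 or arr.shape[0] < 2:
            raise ValueError("need draws from at least 2 chains, shaped (chain, draw, ...)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = np.asarray(az.rhat(az.convert_to_dataset(arr))["x"])
            ess = np.asarray(az.ess(az.convert_to_dataset(arr))["x"])
        # autocorrelation-based ESS estimates can nominally exceed the draw
        # count for anticorrelated chains; cap at the true sample size
        ess = np.minimum(ess, arr.shape[0] * arr.shape[1])
        for idx in np.ndindex(rhat.shape if rhat.shape else (1,)):
            r = float(rhat[idx]) if rhat.shape else float(rhat)
            e = float(ess[idx]) if ess.shape else float(ess)
            label = name if not rhat.shape else f"{name}[{','.join(map(str, idx))}]"
            rows.append({"parameter": label, "rhat": r, "ess": e,
                         "pass": bool(r < rhat_threshold)})
    return pd.DataFrame(rows)


class _ResultsBase:
    """Shared posterior-summary plumbing for both models."""

    def __init__(self, posterior, years, seed, config):
        self.posterior = posterior            # dict: name -> (chain, draw, ...)
        self.years = np.asarray(years)
        self.seed = seed
        self.config = dict(config)
        self._flat = {k: v.reshape((-1,) + v.shape[2:]) for k, v in posterior.items()}

    @property
    def n_draws(self) -> int:
        return next(iter(self._flat.values())).shape[0]

    def draws(self, name: str) -> np.ndarray:
        """Pooled draws of one quantity, chains flattened."""
        return self._flat[name]

    def convergence(self, parameters=None, rhat_threshold: float = 1.05) -> pd.DataFrame:
        parameters = parameters or self._diagnostic_params
        report = check_convergence({p: self.posterior[p] for p in parameters},
                                   rhat_threshold=rhat_threshold)
        return report

    def _warn_if_unconverged(self, rhat_threshold=1.05):
        if next(iter(self.posterior.values())).shape[0] < 2:
            return
        report = self.convergence(rhat_threshold=rhat_threshold)
        self.converged = bool(report["pass"].all())
        self.max_rhat = float(report["rhat"].max())
        if not self.converged:
            warnings.warn(
                f"convergence diagnostics failed for {(~report['pass']).sum()} "
                f"parameter(s); max R-hat = {self.max_rhat:.3f}", stacklevel=3)


class DiscardResults(_ResultsBase):
    """Posterior results of the full (joint reference-species) model."""

    _diagnostic_params = ("sl50", "rl50", "sl50_star", "h")

    def __init__(self, posterior, species, years, mls, seed, config):
        super().__init__(posterior, years, seed, config)
        self.species = list(species)
        self.mls = mls
        self.converged = None
        self.max_rhat = None

    def series_summary(self, quantity: str) -> pd.DataFrame:
        """Median and 95% CI of an annual quantity, per species-year."""
        arr = self.draws(quantity)  # (n, K, T)
        qs = np.quantile(arr, [0.025, 0.5, 0.975], axis=0)
        frames = []
        for k, sp in enumerate(self.species):
            frames.append(pd.DataFrame({
                "species": sp, "year": self.years,
                "median": qs[1, k], "lo": qs[0, k], "hi": qs[2, k]}))
        return pd.concat(frames, ignore_index=True)

    def reference_logq(self, summary: str = "median") -> np.ndarray:
        """Species x year matrix of posterior log catch ratios.

        Posterior medians per species-year (the summary passed to the
        reduced model's weighted geometric mean).
        """
        if summary != "median":
            raise ValueError("only the median summary is supported")
        return np.log(np.quantile(self.draws("Q"), 0.5, axis=0))

    @property
    def h(self) -> float:
        """Posterior median of h = sum RL50 / sum MLS."""
        return float(np.median(self.draws("h")))

    def estimate_h(self) -> float:
        """h recomputed from posterior-median retention lengths."""
        rl50 = np.median(self.draws("rl50"), axis=0)
        return estimate_h(rl50, [self.mls[s] for s in self.species])

    def summary(self) -> pd.DataFrame:
        """Structural-parameter summary table (median and 95% CI)."""
        rows = []
        for name in ("sl50", "si", "rl50", "ri", "sigma_b", "sigma_l", "sigma_d"):
            arr = self.draws(name)
            for k, sp in enumerate(self.species):
                q = np.quantile(arr[:, k], [0.025, 0.5, 0.975])
                rows.append({"parameter": f"{name}[{sp}]", "median": q[1],
                             "lo": q[0], "hi": q[2]})
        for name in ("sl50_star", "sigma_sl50", "h"):
            q = np.quantile(self.draws(name), [0.025, 0.5, 0.975])
            rows.append({"parameter": name, "median": q[1], "lo": q[0], "hi": q[2]})
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready summary of all annual quantities."""
        frames = []
        for qty in ("C", "D", "L", "p", "q", "Q", "u"):
            f = self.series_summary(qty)
            f.insert(0, "quantity", qty)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


class ReducedDiscardResults(_ResultsBase):
    """Posterior results of the reduced (landings-only) model."""

    _diagnostic_params = ("sl50", "w")

    def __init__(self, posterior, species, years, reference_species, seed, config,
                 flags=None):
        super().__init__(posterior, years, seed, config)
        self.species = species
        self.reference_species = list(reference_species)
        self.flags = flags or {}
        self.converged = None
        self.max_rhat = None

    def series_summary(self, quantity: str) -> pd.DataFrame:
        arr = self.draws(quantity)  # (n, T)
        qs = np.quantile(arr, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame({"species": self.species, "year": self.years,
                             "median": qs[1], "lo": qs[0], "hi": qs[2]})

    @property
    def weights_mean(self) -> np.ndarray:
        """Posterior mean Dirichlet blend weights over the reference Q series."""
        return self.draws("w").mean(axis=0)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("sl50", "si", "ri", "sigma_b", "sigma_l"):
            q = np.quantile(self.draws(name), [0.025, 0.5, 0.975])
            rows.append({"parameter": name, "median": q[1], "lo": q[0], "hi": q[2]})
        w = self.draws("w")
        for j, sp in enumerate(self.reference_species):
            q = np.quantile(w[:, j], [0.025, 0.5, 0.975])
            rows.append({"parameter": f"w[{sp}]", "median": q[1], "lo": q[0],
                         "hi": q[2]})
        return pd.DataFrame(rows).set_index("parameter")


class DiscardModel:
    """Joint Bayesian state-space model for the reference species.

    Parameters
    ----------
    observations : sequence of FisheryObservations
        One per reference species; each must carry landings, discards and
        the survey index/length composition on a common year span.
    mls : mapping species -> float
        Minimum landing sizes (cm), the retention-length prior means.
    priors : PriorSet, optional
    """

    def __init__(self, observations, mls, priors: PriorSet | None = None):
        if len(observations) < 2:
            raise ValueError("the full model pools across species; need at least 2")
        for obs in observations:
            if not isinstance(obs, FisheryObservations):
                raise TypeError("observations must be FisheryObservations")
            if obs.discards is None:
                raise ValueError(
                    f"{obs.species}: the full model needs observed discards; "
                    "use ReducedDiscardModel for landings-only species")
            if obs.species not in mls:
                raise ValueError(f"no MLS supplied for {obs.species}")
        self.observations = list(observations)
        self.mls = dict(mls)
        self.priors = priors or full_model_priors()

    @classmethod
    def from_scenario(cls, scenario: dict, priors: PriorSet | None = None) -> "DiscardModel":
        """Build from a :func:`discardcast.simulate.reference_scenario` bundle."""
        obs = [o for _, o in scenario["reference"]]
        return cls(obs, scenario["mls"], priors=priors)

    def fit(self, draws: int = DEFAULT_DRAWS, warmup: int = DEFAULT_WARMUP,
            chains: int = DEFAULT_CHAINS, seed: int | None = None,
            paper_mode: bool = False) -> DiscardResults:
        """Run the MCMC and return a :class:`DiscardResults`.

        ``paper_mode=True`` switches to a single chain of 35,000 retained
        draws after a 15,000-iteration burn-in (no multi-chain R-hat is
        then available).
        """
        if paper_mode:
            chains, warmup, draws = (PAPER_MODE_FULL["chains"],
                                     PAPER_MODE_FULL["warmup"],
                                     PAPER_MODE_FULL["draws"])
        seed = 0 if seed is None else int(seed)
        seeds = np.random.SeedSequence(seed).spawn(chains)
        outputs = []
        for s in seeds:
            sampler = FullModelSampler(self.observations, self.mls, self.priors)
            outputs.append(sampler.run(warmup, draws, np.random.default_rng(s)))
        posterior = _stack_chains(outputs)
        res = DiscardResults(posterior, [o.species for o in self.observations],
                             self.observations[0].years, self.mls, seed,
                             {"draws": draws, "warmup": warmup, "chains": chains})
        res._warn_if_unconverged()
        return res


class ReducedDiscardModel:
    """Single-species model for landings-only species.

    Parameters
    ----------
    observations : FisheryObservations
        Landings + survey index (discards, if present, are ignored).
    reference_logq : ndarray (n_reference, n_years)
        Posterior-median log catch ratios from a full-model fit
        (``DiscardResults.reference_logq()``).
    mls : float
        Minimum landing size (cm) of this species.
    h : float
        Retention proportionality constant from the full fit; the
        retention length is fixed at h x MLS.
    priors : PriorSet, optional
        Defaults to the low-value-species priors (flat Beta(1,1) on q).
    value_class : 'low' or 'high'
        Convenience switch selecting the default q prior when ``priors``
        is not given.
    qmean : 'geometric' or 'arithmetic'
        How the reference Q series are blended (sensitivity switch).
    reference_species : sequence of str, optional
        Names for the weight vector.
    """

    def __init__(self, observations: FisheryObservations, reference_logq,
                 mls: float, h: float, priors: PriorSet | None = None,
                 value_class: str = "low", qmean: str = "geometric",
                 reference_species=None):
        if reference_logq is None:
            raise ValueError("reference_logq from a completed full-model fit is required")
        self.observations = observations
        self.reference_logq = np.asarray(reference_logq, dtype=float)
        self.mls = float(mls)
        self.h = float(h)
        self.priors = priors or reduced_model_priors(value_class)
        self.qmean = qmean
        self.reference_species = (list(reference_species) if reference_species
                                  else [f"ref_{j}" for j in
                                        range(self.reference_logq.shape[0])])

    def fit(self, draws: int = DEFAULT_DRAWS, warmup: int = DEFAULT_WARMUP,
            chains: int = 2, seed: int | None = None,
            paper_mode: bool = False) -> ReducedDiscardResults:
        if paper_mode:
            chains, warmup, draws = (PAPER_MODE_REDUCED["chains"],
                                     PAPER_MODE_REDUCED["warmup"],
                                     PAPER_MODE_REDUCED["draws"])
        seed = 0 if seed is None else int(seed)
        seeds = np.random.SeedSequence(seed).spawn(chains)
        outputs = []
        flags = {}
        for s in seeds:
            sampler = ReducedModelSampler(
                self.observations, self.reference_logq, self.mls, self.h,
                self.priors, qmean=self.qmean)
            outputs.append(sampler.run(warmup, draws, np.random.default_rng(s)))
            flags["index_missing_years"] = int(sampler.q_fixed.sum())
            flags["all_index_missing"] = sampler.all_index_missing
        posterior = _stack_chains(outputs)
        res = ReducedDiscardResults(posterior, self.observations.species,
                                    self.observations.years,
                                    self.reference_species, seed,
                                    {"draws": draws, "warmup": warmup,
                                     "chains": chains, "qmean": self.qmean},
                                    flags=flags)
        res._warn_if_unconverged()
        return res
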