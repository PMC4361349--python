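"""Prior specifications for the full (joint reference-species) and reduced
(single landings-only species) models.

Normal priors are parameterised by a standard deviation by default; set
``normal_scale_is_sd=False`` to read the second argument as a BUGS-style
precision instead.  Normal priors on selection intervals and retention
lengths are truncated below at 0.5 cm: a logistic ogive needs a positive
interval, and a retention length of essentially zero is structurally
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PriorSet", "full_model_priors", "reduced_model_priors"]

TRUNC_LOW = 0.5  # cm; lower truncation for SI, RI and RL50 normals


@dataclass(frozen=True)
class PriorSet:
    """Named prior hyperparameters.

    Full model: SL50* ~ Uniform(*sl50_star_bounds*); species SL50s are the
    common mean plus a Normal(0, sigma_SL50) random effect with
    sigma_SL50 ~ Uniform(*sigma_sl50_bounds*); SI, RI ~ Normal(*si_prior*);
    RL50_k ~ Normal(MLS_k, *rl50_sd*); q_t ~ Beta(*q_beta*); all precisions
    ~ Gamma(*precision_gamma*) (shape, rate); log u_1 ~ Normal(log mean
    observed index, *logu1_sd*); log Q_1 ~ Uniform(*logq1_bounds*).

    Reduced model: SL50 ~ Normal(*sl50_reduced*); q_t ~ Beta(1, 1) for
    low-value species or Beta(1.4, 12) for high-value species; blend
    weights ~ Dirichlet(*dirichlet_alpha*).
    """

    sl50_star_bounds: tuple = (5.0, 30.0)
    sigma_sl50_bounds: tuple = (0.0, 100.0)
    si_prior: tuple = (6.0, 1.414)
    ri_prior: tuple = (6.0, 1.414)
    rl50_sd: float = 7.76
    q_beta: tuple = (0.5, 3.0)
    precision_gamma: tuple = (0.1, 0.1)
    logu1_sd: float = 0.5
    logq1_bounds: tuple = (2.0, 14.0)
    sl50_reduced: tuple = (15.25, 4.93)
    dirichlet_alpha: float = 1.0
    normal_scale_is_sd: bool = True
    trunc_low: float = TRUNC_LOW

    def sd(self, scale: float) -> float:
        """Interpret a Normal scale argument (sd, or precision if configured)."""
        return scale if self.normal_scale_is_sd else 1.0 / np.sqrt(scale)

    @property
    def q_prior_mean(self) -> float:
        a, b = self.q_beta
        return a / (a + b)

    def with_(self, **kwargs) -> "PriorSet":
        return replace(self, **kwargs)


def full_model_priors(**overrides) -> PriorSet:
    """Default priors for the joint reference-species model."""
    return PriorSet(**overrides)


def reduced_model_priors(value_class: str = "low", **overrides) -> PriorSet:
    """Default priors for a landings-only species.

    ``value_class='low'`` uses a flat Beta(1, 1) on the bulk-discard
    fraction (no presumption against quantity discarding of low-value
    species); ``'high'`` uses Beta(1.4, 12), an informative prior matched
    to the reference-species posterior (mean ~0.104).
    """
    if value_class not in {"low", "high"}:
        raise ValueError("value_class must be 'low' or 'high'")
    q_beta = (1.0, 1.0) if value_class == "low" else (1.4, 12.0)
    return PriorSet(q_beta=q_beta, **overrides)
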