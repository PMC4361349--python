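# Methods

## The model

`discardcast` estimates annual quantities of fish discarded at sea from two
data streams that exist for nearly every commercially exploited species —
official landed weights and research-vessel trawl-survey length
compositions — rather than from scarce on-board observer data.

For each species and year *t*, the survey supplies a biomass index *u'ₜ*
(kg km⁻², summed over 1-cm length classes) and length proportions *πᵢ,ₜ*.
The latent total catch and discards are

    Cₜ = uₜ Qₜ Σᵢ s'ᵢ πᵢ,ₜ
    Dₜ = uₜ Qₜ ( Σᵢ s'ᵢ πᵢ,ₜ + (qₜ − 1) Σᵢ rᵢ s'ᵢ πᵢ,ₜ )
    Lₜ = Cₜ − Dₜ

where *uₜ* is the latent survey index, *Qₜ* a catch ratio (the product of
survey catchability and annual harvest rate — any unit mismatch between
index and landings is absorbed here, not corrected), *s'ᵢ* the capture
selectivity of the commercial fleet relative to the survey's size
perception, *rᵢ* the on-board retention selectivity, and *qₜ* ∈ [0, 1] an
annual "bulk" (quantity-related) discard fraction applied regardless of
size.  Both ogives are two-parameter logistics, parameterised by the 50%
selection length and the 25–75% selection interval:
logit s(l) = ln 9 / SI · (l − SL50).  Discards partition into a
quantity-selected component qₜCₜ and a size-selected remainder Dₜ − qₜCₜ.

*uₜ* and *Qₜ* follow multiplicative random walks (log-scale Gaussian
increments with sds σᵤ, σ_Q), which separates process from measurement
noise.  Observed index, landings and discards are lognormal around the
latent truths with sds σ_b, σ_l, σ_d.  The likelihood convention is the
normal density of the log-observation (so a zero residual at σ = 1
contributes −½ ln 2π); this pins down the additive constants for testing.

**Full model.** Fitted jointly to the reference species (those with
observed discard series; five in the default scenario, mirroring cod,
haddock, whiting, plaice and sole).  Capture 50%-lengths are pooled:
SL50ₖ = SL50* + eₖ, eₖ ~ N(0, σ_SL50).  Priors: SL50* ~ U(5, 30),
σ_SL50 ~ U(0, 100), SI, RI ~ N(6, 1.414), RL50ₖ ~ N(MLSₖ, 7.76),
qₜ ~ Beta(0.5, 3), all precisions ~ Gamma(0.1, 0.1) (shape, rate),
log u₁ ~ N(log mean observed index, 0.5), log Q₁ ~ U(2, 14).  The second
argument of every Normal prior is a standard deviation by default; a
`PriorSet` switch reads it as a precision instead (the parent analysis of
this model family was coded in BUGS, where precision is the convention).
The flat U(5, 30) is placed on the common mean SL50*: that is the only
coherent joint reading of a flat prior plus the hierarchical decomposition.
Normals on SI, RI and RL50 are truncated below at 0.5 cm — a logistic ogive
needs a positive interval; the truncation is this package's choice.

**Reduced model.** For a species with landings and index only, capture and
retention cannot be estimated freely.  SL50 gets the informative prior
N(15.25, 4.93) (the reference-case posterior); RL50 is fixed at h·MLS with
h = ΣRL50ₖ / ΣMLSₖ from the full fit; and log Qₜ = Σₖ wₖ log Q₍ₖ,ₜ₎ — a
weighted geometric mean of the reference species' posterior-median log
catch-ratio series, with w ~ Dirichlet(1,…,1) estimated from the landings.
Posterior medians (not full posterior draws) are the Q summary passed
through the blend; the point-summary choice is documented here because the
alternative (propagating reference-Q uncertainty) would widen the reduced
model's intervals further.  An arithmetic-mean blend is available as a
sensitivity switch.  The q prior is Beta(1, 1) for low-value species and
Beta(1.4, 12) (mean ≈ 0.104) for high-value species.  Years with a zero
(hence missing) survey index use the unweighted across-year mean length
composition and pin qₜ at its prior mean; a fit where every index year is
missing still completes, with flags on the results object.

## Sampling

No probabilistic-programming backend is used; the sampler is a purpose-
built adaptive Metropolis-within-Gibbs:

- precisions (observation and random-walk) have conjugate Gamma full
  conditionals; the pooled SL50* has a truncated-normal full conditional;
  σ_SL50 reduces to a truncated Gamma draw on the precision scale;
- the random-walk states log uₜ and log Qₜ are Markov in *t*, so alternate
  (checkerboard) years are updated simultaneously with independent
  single-site Gaussian proposals, vectorised across species and years;
- qₜ is updated on the logit scale (Beta prior absorbed with its Jacobian),
  all years at once; the simplex w through softmax coordinates with the
  log-determinant Σ log wₖ;
- ogive parameters are single-site Metropolis per species, recomputing the
  composition-weighted selection sums (a small matrix product) on proposal;
- a compensated exchange move proposes (log uₜ + d, log Qₜ − d) jointly:
  the sum is pinned tightly by landings and discards, so the orthogonal
  direction would otherwise mix very slowly.

Initial states solve the model exactly per year given the starting ogives
(x from the observed index; C' = L' + D' fixes u·Q; the landed share fixes
q), and the starting RL50 is calibrated by bisection so the implied q path
is feasible (q ≥ 0 in every year).  Starting inside this high-likelihood
region matters: the precision/state Gibbs cascade descends into it only
very slowly from a generic start.

Step sizes adapt per site during warm-up (Robbins–Monro on the log step,
target acceptance 0.44, diminishing adaptation) and are frozen for the
retained draws, so the recorded chain is a valid Markov chain.  Default
testing configuration: 4 chains × (2,000 warm-up + 2,000 retained);
`paper_mode=True` switches to the long single-chain configurations
(full: 15,000 burn-in + 35,000 retained; reduced: the printed 50,000/15,000
pair, kept verbatim although the ordering is unusual).  Convergence is
summarised by split-R̂ and ESS (arviz), with a warning — never a silent
pass — when R̂ exceeds 1.05.  Every fit takes an explicit seed; chains get
independent `SeedSequence`-spawned streams.

Numerical safeguards: D's factor S + (q−1)R is strictly positive whenever
some length class is below full retention, so log-scale work is safe; q
never reaches 0/1 exactly on the logit scale; proposal exponentials are
clipped to avoid overflow.

**Identifiability of the error scales.** With a free (uₜ, Qₜ, qₜ) triple
per year the observation model is saturated — the states can interpolate
any data — so the observation sds σ_b, σ_l, σ_d are only weakly identified:
their posteriors sit where the Gamma priors and the state-prior volume put
them (around 0.05–0.15 under Gamma(0.1, 0.1) at these series lengths),
even when the generating noise is far smaller.  Regularisation comes from
the random-walk smoothness, the Beta prior on q, the q ∈ [0, 1] feasibility
boundary, and the cross-year sharing of the ogive parameters; these are
what make the discard hind-casts informative.  A consistency check at
near-zero noise therefore has to supply the known noise scale through the
precision prior (e.g. Gamma(2, 2σ²)); the tests do exactly that, and the
posterior median discards then track truth to within 2%.  Per-species SL50
normals are truncated to (5, 30) cm: below the composition's support the
likelihood is flat in SL50, and without bounds the random effect wanders
unphysically.

## Synthetic data

The generator produces data with exactly the structure the model assumes:
random-walk Q and u (σ_Q = 0.15, σᵤ = 0.10), Beta(0.5, 3) annual q,
hierarchical SL50 (mean 15.25 cm, sd 2 cm), SI = RI = 6 cm, retention at
h·MLS with h = 0.874, observation sds σ_b = 0.15, σ_l = 0.10, σ_d = 0.20,
34 years, and minimum landing sizes 35/30/27/27/24 cm for the five
reference species.  Length compositions are discretised normals (sd 6–7 cm,
mean near the MLS so both ogive limbs see biomass); a shape function can be
plugged in.  Landings-only species take Q paths that are Dirichlet-weighted
geometric blends of the reference paths — matching the reduced model's
assumption, which is what makes the cross-validation structure testable.
Haul tables draw Poisson counts from number density × swept area, giving a
realistic route from hauls to a noisy index.

What the generator does *not* emulate: spatial structure and gear changes,
time-varying selectivity, within-survey correlation between length classes
beyond the smooth shape, mis-reported landings, and model mis-specification
in general.  Passing recovery tests therefore demonstrates internal
consistency of model + sampler under the model's own assumptions, not
robustness to the ways real survey and landings data violate them.

## Survey processing

Swept area is tow distance × wing spread; where geometry is missing it is
imputed from a log-linear regression of area on tow duration and seabed
depth fitted to the complete hauls of the same table (the published
external relationship for this imputation is not reproducible from its
citation, so the regression is fitted from the data at hand).  Number
densities are means over all hauls of count/area (zero-catch hauls count);
biomass conversion uses weight = a·lᵇ at the 1-cm class midpoint (the
midpoint is unbiased for 1-cm bins; measured lengths are cm-below).
Zero-index years are missing, not zero.  Taxa can be collapsed by a
mapping table; unmapped taxa route to a "discard-only" group.  Counts are
assumed raised to haul totals; a subsample-factor column is honoured if
present.

## Validation machinery

- **Cross-validation** refits each reference species with the reduced model
  leave-discards-out (the species' own Q series stays a candidate) and
  reports the weight matrix, whose diagonal should dominate.
- **q-from-age** gives a crude independent check of the bulk-discard
  fraction: a knife-edge threshold at weight(MLS + 1 cm), with q̂ the
  discarded share of supra-threshold catch weight.
- **compare_p** compares inverse-logit means of sporadic observed discard
  proportions with model means over a window, species by species
  (observations averaged on the logit scale, the model on the natural
  scale; p = 1 fragments excluded).
- **Sensitivity** perturbs one parameter at a time by ±10% under a fixed
  seed, reporting the signed % change in mean discards; RL50 dominates for
  species with narrow length ranges, as the forward model's geometry
  dictates.
- **Assemblage aggregation** is strictly draw-wise: totals, overall
  discard rate ΣD/ΣC, the size/quantity split and group shares are computed
  per retained draw and only then summarised, so intervals are of sums.
- **r²** is defined as 1 − SS_res/SS_tot of observations about the
  posterior-median series (can be negative).

## Problem sizes and defaults

The shipped tests and the acceptance script use the default scenario
(5 reference + 3 other species, 34 years) with 4 × (2,000 + 2,000) MCMC for
the full model and 2 × (1,000 + 1,000) for each reduced fit — sizes chosen
as the package's standard desk-scale configuration; one full fit takes on
the order of a minute on a single core.  Decade summaries use calendar
decades (1980s = 1980–1989).  Known limitations: single-site Metropolis
mixes slowly for strongly correlated ogive parameters (R̂ warnings at small
chain lengths are expected and surfaced, not hidden); the reduced model
conditions on point summaries of the reference Q series; and the identity
of the q partition rests on the assumed logistic retention form.
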