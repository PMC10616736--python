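# Methods

## Model

`msocc` implements a single-season multistate occupancy model with three
latent states per site-year, z ∈ {0 = unoccupied, 1 = adults only,
2 = adults with cubs}, and three observable states y per monthly occasion
(none / adults / cubs).  With ψ_i the probability adults use site i at least
once during a season and R_i the probability cubs use it conditional on
adult use, the state prior is

    Pr(z) = (1 − ψ_i,  ψ_i(1 − R_i),  ψ_i R_i).

Both ψ and R are logit-linear in a standardized landscape-scale habitat
proportion (5-km radius) and a two-level ecoregion indicator (Great Basin is
the reference level), each with a per-site Normal(0, σ²) random intercept
shared across that site's years:

    logit ψ_i = α_ψ + u_i^ψ + β1_ψ · habitat5km_i + β2_ψ · [SierraNevada_i]
    logit R_i = α_R + u_i^R + β1_R · habitat5km_i + β2_R · [SierraNevada_i]

Detection is multinomial per occasion with three logit-linear probabilities
in local (1-km) habitat: p22 = Pr(detect adults | z = 1), p23 = Pr(observe
adults only | z = 2), p33 = Pr(observe cubs | z = 2).  False positives are
assumed absent, so the observation matrix rows are (1, 0, 0),
(1 − p22, p22, 0) and (1 − p23 − p33, p23, p33); observing a cub therefore
proves z = 2, while z = 2 sites can be misrecorded as adults-only or
missed — the one direction of misclassification the model tolerates.
Missing occasions (camera inactive) contribute a factor of one to the
likelihood.  Years are stacked as independent site-year replicates that
share their site's covariates and random effects; there is no
colonization/extinction dynamic and no year effect.

Key modelling assumptions: closure within a nine-month season (a site "used
at least once" is treated as occupied throughout), no false positives,
occasion-level independence given z, and exchangeable occasions (the
likelihood depends on a site-year's history only through its counts of
adult-only and cub observations and active occasions — which is also how
the implementation computes it).

## Priors and the detection constraint

All twelve fixed effects and detection coefficients get Normal(0, sd 10)
priors; the two random-effect standard deviations get Uniform(0, 10)
(both configurable via `PriorSpec`).  Independent logit-linear p23 and p33
do not automatically satisfy p23 + p33 ≤ 1; a parameter state violating the
constraint at any site is assigned prior support zero, which the sampler
consumes as an automatic proposal rejection.  In the realistic parameter
range (p23 ≈ 0.5, p33 ≈ 0.2) the constraint essentially never binds.  A
multinomial-logit reparameterization would remove the constraint but would
change the meaning of the reported coefficients, so the direct
parameterization is the only one implemented.

## Inference

Sampling is Metropolis-within-Gibbs with latent-state augmentation:

1. z-step — each site-year's z is drawn from its exact full conditional
   Pr(z | y, θ) ∝ φ[z] Π_t θ[z, y_t] (a Gumbel-max categorical draw over
   the three states; states incompatible with the observations get
   probability zero).
2. Parameter step — given z the complete-data likelihood factorizes into
   four pieces (state prior in ψ; conditional prior in R; binomial adult
   detection; trinomial cub-state detection), each a function of per-site
   sufficient statistics.  Scalar coefficients update by random-walk
   Metropolis; the per-site random effects are conditionally independent
   given z and update as a vectorized element-wise Metropolis block; the two
   random-effect sds update by Metropolis on log σ (with the log-transform
   Jacobian) against the Uniform(0, 10) prior.

Proposal scales start at 0.1 and adapt every 50 iterations during burn-in
only, toward a 0.35 acceptance rate with a decaying step size; the
post-burn-in kernel is fixed, so the retained draws target the exact
posterior.  Latent states start at the maximum state ever observed at each
site-year (the only assignment guaranteed compatible with the data);
parameters start from seeded overdispersed draws, re-drawn if they violate
the detection constraint.  Chain c uses an independent substream of the root
seed (`numpy` `SeedSequence.spawn`), making every run bit-reproducible.

Convergence uses the classic (non-split) Gelman–Rubin statistic,
Rhat = sqrt(((n−1)/n · W + B/n) / W), with Rhat < 1.1 taken as converged;
a split-chain variant is available via `gelman_rubin(..., split=True)`.
The default protocol is 3 chains × 200,000 iterations, 100,000 burn-in,
thinning 40 — 2,500 retained draws per chain, 7,500 total.

## Predictions

Prediction interfaces take raw habitat proportions in [0, 1] and
standardize them internally with the constants stored at fit time, computed
over the analysis sites only.  The random effect is handled by policy:
`typical` (the default) evaluates the conditional-median site (u = 0);
`marginal` integrates the response over Normal(0, σ²) per retained draw by
21-node Gauss–Hermite quadrature.  The typical-site curve is
steeper/narrower; the marginal curve is attenuated toward 0.5.  Both are
defensible summaries; `typical` is the default because it is the
smaller-variance convention.  State counts per year are tallied from the
retained latent-state draws (so they respect the data: a site with an
observed cub can never count as unoccupied), and "total occupied" is
adults-only plus with-cubs.

## Synthetic data

The generator runs the model forward under a design mirroring the
motivating camera-trap study: 100 sites, 11 Sierra Nevada / 89 Great Basin,
3 years × 9 monthly occasions, first-season cameras active from occasion 3
(mid-year deployment), and 5% random occasion loss (camera failure).
Habitat proportions are Beta(2, 2) in the Great Basin (spanning the full
gradient) and Beta(5, 2) in the Sierra Nevada; the 1-km and 5-km
proportions are coupled by a Gaussian copula with correlation 0.7 — a
deliberately simple stand-in for the nested-scale dependence of real
land-cover summaries.

The default generating truth puts the slope coefficients at the fitted
scale of the motivating analysis (habitat 2.1 / 1.7 on occupancy /
reproduction; ecoregion 5.8 / 3.3; detection habitat 0.8 / 0.0 / −0.1) and
the random-effect sds at 0.45^(−1/2) ≈ 1.49 and 1.97^(−1/2) ≈ 0.71.  That
analysis printed no intercepts; the defaults here (−1.5 occupancy, −1.0
reproduction, detection −1.7 / −0.1 / −1.2) were chosen once so that mean
Great Basin adult occupancy is ≈ 0.3, conditional reproduction ≈ 0.32, and
monthly detection probabilities ≈ 0.15 / 0.48 / 0.23 — plausible baseline
rates for this system — and are documented as fixture choices, not
estimates.

What the generator does *not* emulate: spatial autocorrelation among sites,
year effects (mast years), within-season heterogeneity in detection,
observer misclassification of cubs as adults, and cub mortality during the
season.  Passing recovery tests therefore demonstrate that the estimator
recovers the parameters of its own generative model at the study's design
size — not that the model is correctly specified for field data.

## Numerical choices

- All probabilities go through `scipy.special.expit` / `log_expit`; the
  likelihood is computed on per-site-year sufficient statistics (active
  occasions, adult-only count, cub count), never per occasion.
- 0 · log 0 terms (e.g. no cub observations with p33 = 0) contribute 0;
  a history that *requires* an impossible observation yields −inf, and a
  −inf log posterior at initialization raises an error naming the offending
  likelihood piece.
- Standardization uses the n−1 sample sd; a constant covariate is an error,
  not a silent drop.
- Credible intervals are central 95% (2.5/97.5 percentiles); ties and
  ordering in state tallies are irrelevant because counts are sums.

## Scaled-down protocols

Tests and the acceptance script fit with 3 chains × 20,000 iterations
(10,000 burn-in, thin 10) on the 100-site design, and run 10–20 replicate
recovery experiments at that size; the toy posterior-correctness check uses
10^5 retained draws of a single free intercept.  These sizes were chosen as
the smallest at which the corresponding checks are statistically meaningful.

## Known limitations

- Under the diffuse Normal(0, 10) priors, datasets in which an ecoregion is
  fully occupied (quasi-separation — likely whenever the true Sierra Nevada
  occupancy is ≈ 1 with 11 sites) leave the ecoregion coefficients
  identified only from below; their posterior means then sit well above any
  finite truth and are prior-sensitive.  This is a property of the model
  and priors, not of the sampler.  A practical consequence,
  visible in the packaged recovery experiment, is that the frequentist
  coverage of 95% credible intervals for the habitat and ecoregion slopes
  falls somewhat below nominal at the default study size: when a simulated
  dataset is (nearly) separable the whole interval can sit above the
  generating value.  Tighter, weakly-informative priors would restore
  coverage at the cost of changing the reported estimand.
- The habitat slopes inherit some of this inflation in small or
  weakly-detecting datasets (posterior skew under near-separation).
- Random-effect sds mix slowly when few sites are occupied (little
  information about σ_R); Rhat flags this, and longer chains are the
  remedy.
- The direct multinomial detection parameterization requires
  p23 + p33 ≤ 1; fits where the posterior pushes against that boundary
  would mix poorly (not observed in the realistic range).
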