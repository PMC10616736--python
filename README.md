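# msocc

Bayesian **m**ulti**s**tate **occ**upancy modelling for detection/non-detection
surveys that distinguish *reproduction* from mere presence — e.g. camera-trap
studies of black bears where photos are classified as "no bear", "adult bear"
or "cub", and the question is how adult occupancy and the conditional
probability of cub occupancy change along habitat gradients toward a range
boundary.

## The model

Each site-year has a latent state z ∈ {0 unoccupied, 1 adults only,
2 adults with cubs} with prior

    Pr(z) = (1 − ψᵢ,  ψᵢ(1 − Rᵢ),  ψᵢRᵢ),

where ψᵢ is adult occupancy and Rᵢ cub occupancy conditional on adults.
Both are logit-linear in standardized landscape habitat (5-km radius) and an
ecoregion indicator (Great Basin reference level), with per-site random
intercepts shared across years:

    logit ψᵢ = α₁ψ + α₂ᵢψ + β₁ψ·habitat5kmᵢ + β₂ψ·Ecoregionᵢ
    logit Rᵢ = α₁R + α₂ᵢR + β₁R·habitat5kmᵢ + β₂R·Ecoregionᵢ

Observation per monthly occasion is multinomial with no false positives:
p22 = Pr(detect adults | z = 1), p23 = Pr(observe adults only | z = 2),
p33 = Pr(observe cubs | z = 2), each logit-linear in local (1-km) habitat.
Cubs can be missed or recorded as adults; they are never invented.
Inference is Metropolis-within-Gibbs with exact latent-state augmentation,
burn-in-only proposal adaptation, classic Gelman–Rubin convergence
diagnostics (Rhat < 1.1), and full seed-level reproducibility.  See
`docs/methods.md` for assumptions, priors and numerical details.

## Worked example

```python
import msocc

# simulate a study like the motivating design: 100 sites (11 Sierra Nevada,
# 89 Great Basin), 3 years x 9 monthly occasions
history, cov, truth = msocc.simulate_study(msocc.SimulationDesign(seed=1))

model = msocc.MultistateOccupancy(
    n_chains=3, n_iterations=20_000, burn_in=10_000, thin=10, seed=1,
).fit(history, cov)

print(model.summary_.loc[["occ_habitat", "occ_ecoregion",
                          "rep_habitat", "rep_ecoregion"],
                         ["mean", "q2.5", "q97.5", "rhat"]].round(2))
print(model.predict(0.5, ecoregion="GreatBasin").round(2))
```

prints (numbers from this exact run):

```
                mean  q2.5  q97.5  rhat
parameter
occ_habitat     2.02  1.25   3.04  1.01
occ_ecoregion  12.03  4.96  23.85  1.00
rep_habitat     3.74  1.39   8.26  1.02
rep_ecoregion   5.79  1.85  12.92  1.01
   habitat5km   ecoregion  psi_mean  psi_lo  psi_hi  R_mean  R_lo  R_hi
0         0.5  GreatBasin      0.13    0.06    0.22    0.11   0.0  0.33
```

All four slope coefficients are recovered with the right sign and their
95% intervals cover the generating truth (habitat 2.1 / 1.7, ecoregion
5.8 / 3.3).  The ecoregion coefficients are only bounded from below when
every Sierra Nevada site is occupied, so their posterior means sit high
with wide intervals — see `docs/methods.md`.  The last line gives posterior-mean adult occupancy
and conditional cub occupancy, with 95% credible intervals, for a typical
Great Basin site whose landscape is 50% habitat.  `model.state_counts(year)`
tallies how many of the 100 sites are estimated unoccupied / adults-only /
with-cubs in a year, and `model.predict_grid(...)` evaluates ψ and R over
any covariate table.

The same pipeline is scriptable: `msocc simulate`, `msocc fit`,
`msocc predict`, `msocc diagnose`, each driven by a flat `key = value`
config file (see `msocc --help`).

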