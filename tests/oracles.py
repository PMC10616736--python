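"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops and closed forms,
no shared code with the package internals beyond the public data containers.
"""

import math

import numpy as np

from msocc.io import MISSING


def enumerate_marginal(y, phi, theta):
    """Brute-force marginal likelihood of one site-year: sum over the three
    latent states of prior x product of per-occasion observation probs."""
    total = 0.0
    for z in range(3):
        p = phi[z]
        for yt in y:
            if yt is None or yt == MISSING or (isinstance(yt, float) and math.isnan(yt)):
                continue
            p *= theta[z][int(yt)]
        total += p
    return math.log(total) if total > 0 else -math.inf


def linear_predictors_naive(cov, params, site):
    """Hand-coded logit-scale predictors for one site."""
    x5 = cov.standardized_habitat5km[site]
    x1 = cov.standardized_habitat1km[site]
    sn = 1.0 if cov.ecoregion[site] == "SierraNevada" else 0.0
    u_occ = 0.0 if params.occ_random_effects is None else params.occ_random_effects[site]
    u_rep = 0.0 if params.rep_random_effects is None else params.rep_random_effects[site]
    lpsi = params.occ_intercept + u_occ + params.occ_beta_habitat * x5 \
        + params.occ_beta_ecoregion * sn
    lR = params.rep_intercept + u_rep + params.rep_beta_habitat * x5 \
        + params.rep_beta_ecoregion * sn
    dets = [a + b * x1 for a, b in zip(params.det_intercepts, params.det_beta_habitat)]
    return lpsi, lR, dets


def _ilogit(x):
    return 1.0 / (1.0 + math.exp(-x)) if x > -700 else math.exp(x)


def total_loglik_naive(history, cov, params):
    """Double loop over sites and years, enumeration per site-year."""
    total = 0.0
    for i in range(history.n_sites):
        lpsi, lR, (l22, l23, l33) = linear_predictors_naive(cov, params, i)
        psi, R = _ilogit(lpsi), _ilogit(lR)
        p22, p23, p33 = _ilogit(l22), _ilogit(l23), _ilogit(l33)
        phi = [1 - psi, psi * (1 - R), psi * R]
        theta = [[1, 0, 0], [1 - p22, p22, 0], [1 - p23 - p33, p23, p33]]
        for j in range(history.n_years):
            y = [MISSING if history.missing_mask[i, j, t]
                 else int(history.observed_state[i, j, t])
                 for t in range(history.n_occasions)]
            total += enumerate_marginal(y, phi, theta)
    return total


def two_state_loglik(history, cov, params):
    """Standard single-season two-state occupancy likelihood (no cub state):
    L = psi * prod Bern(y_t; p22) + (1 - psi) * 1{all y_t = 0} per site-year.
    Valid only for histories without observed state 2."""
    total = 0.0
    for i in range(history.n_sites):
        lpsi, _, (l22, _, _) = linear_predictors_naive(cov, params, i)
        psi, p22 = _ilogit(lpsi), _ilogit(l22)
        for j in range(history.n_years):
            prod = 1.0
            all_zero = True
            any_obs = False
            for t in range(history.n_occasions):
                if history.missing_mask[i, j, t]:
                    continue
                any_obs = True
                yt = int(history.observed_state[i, j, t])
                assert yt in (0, 1)
                prod *= p22 if yt == 1 else 1.0 - p22
                if yt != 0:
                    all_zero = False
            if not any_obs:
                continue
            total += math.log(psi * prod + (1.0 - psi) * (1.0 if all_zero else 0.0))
    return total
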