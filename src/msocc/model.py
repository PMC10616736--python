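"""Multistate occupancy likelihood with a reproduction (conditional) state.

The latent state of a site-year is z in {0 = unoccupied, 1 = adults only,
2 = adults with cubs}.  With psi_i the probability site i is occupied by
adults and R_i the probability cubs occupy it conditional on adult occupancy,
the state prior is

    Pr(z) = (1 - psi_i,  psi_i (1 - R_i),  psi_i R_i).

Both psi and R are logit-linear in standardized landscape-scale habitat and
an ecoregion indicator (GreatBasin = reference), each with a per-site random
intercept shared across years:

    logit(psi_i) = a_psi + u_i^psi + b1_psi * habitat5km_i + b2_psi * SN_i
    logit(R_i)   = a_R   + u_i^R   + b1_R   * habitat5km_i + b2_R   * SN_i

Detection is a per-occasion multinomial with three logit-linear probabilities
in local (1 km) habitat: p22 (detect adults | z = 1), p23 (observe adults
only | z = 2) and p33 (observe cubs | z = 2).  False positives do not occur:
the observed state never exceeds z, so the observation matrix rows are

    z = 0:  (1, 0, 0)
    z = 1:  (1 - p22, p22, 0)
    z = 2:  (1 - p23 - p33, p23, p33)       with p23 + p33 <= 1.

The likelihood marginalizes z per site-year; missing occasions contribute a
factor of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .io import MISSING, DetectionHistory, SiteCovariates

__all__ = [
    "FIXED_PARAM_NAMES",
    "ModelParameters",
    "PriorSpec",
    "ConstraintViolation",
    "inv_logit",
    "state_probs",
    "observation_matrix",
    "occupancy_and_reproduction",
    "detection_probs",
    "site_year_marginal_loglik",
    "total_loglik",
    "log_prior",
    "SuffStats",
]

#: Order of the scalar parameters in flattened draw arrays.
FIXED_PARAM_NAMES = (
    "occ_intercept", "occ_habitat", "occ_ecoregion",
    "rep_intercept", "rep_habitat", "rep_ecoregion",
    "p22_intercept", "p22_habitat",
    "p23_intercept", "p23_habitat",
    "p33_intercept", "p33_habitat",
    "occ_re_sd", "rep_re_sd",
)


class ConstraintViolation(ValueError):
    """The multinomial detection constraint p23 + p33 <= 1 is violated.

    The MCMC sampler consumes this as an automatic proposal rejection."""


def inv_logit(x):
    """Numerically stable inverse logit, strictly in (0, 1) for finite x."""
    return expit(x)


def state_probs(psi: float, R: float) -> np.ndarray:
    """State prior (1-psi, psi(1-R), psi R); sums to one by construction."""
    return np.array([1.0 - psi, psi * (1.0 - R), psi * R])


def observation_matrix(p22: float, p23: float, p33: float) -> np.ndarray:
    """Row-stochastic 3x3 observation matrix theta[z, y].

    Raises :class:`ConstraintViolation` when p23 + p33 > 1 (the z = 2 row
    would not be a probability vector).
    """
    if p23 + p33 > 1.0:
        raise ConstraintViolation(f"p23 + p33 = {p23 + p33:.4f} > 1")
    return np.array([
        [1.0, 0.0, 0.0],
        [1.0 - p22, p22, 0.0],
        [1.0 - p23 - p33, p23, p33],
    ])


@dataclass(frozen=True)
class ModelParameters:
    """Every parameter of the multistate occupancy model.

    Random-effect vectors may be ``None`` (interpreted as all-zero, e.g. for
    a "typical site"); standard deviations are on the natural scale.
    """

    occ_intercept: float = 0.0
    occ_beta_habitat: float = 0.0
    occ_beta_ecoregion: float = 0.0
    rep_intercept: float = 0.0
    rep_beta_habitat: float = 0.0
    rep_beta_ecoregion: float = 0.0
    det_intercepts: tuple = (0.0, 0.0, 0.0)       # (p22, p23, p33)
    det_beta_habitat: tuple = (0.0, 0.0, 0.0)     # (p22, p23, p33)
    occ_re_sd: float = 1.0
    rep_re_sd: float = 1.0
    occ_random_effects: np.ndarray | None = field(default=None, repr=False)
    rep_random_effects: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.occ_re_sd <= 0 or self.rep_re_sd <= 0:
            raise ValueError("random-effect standard deviations must be positive")
        for name in ("occ_random_effects", "rep_random_effects"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    @property
    def occ_precision(self) -> float:
        return self.occ_re_sd ** -2

    @property
    def rep_precision(self) -> float:
        return self.rep_re_sd ** -2

    def random_effects(self, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
        occ = self.occ_random_effects
        rep = self.rep_random_effects
        return (
            np.zeros(n_sites) if occ is None else occ,
            np.zeros(n_sites) if rep is None else rep,
        )

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def fixed_vector(self) -> np.ndarray:
        """The 14 scalar parameters in :data:`FIXED_PARAM_NAMES` order."""
        return np.array([
            self.occ_intercept, self.occ_beta_habitat, self.occ_beta_ecoregion,
            self.rep_intercept, self.rep_beta_habitat, self.rep_beta_ecoregion,
            self.det_intercepts[0], self.det_beta_habitat[0],
            self.det_intercepts[1], self.det_beta_habitat[1],
            self.det_intercepts[2], self.det_beta_habitat[2],
            self.occ_re_sd, self.rep_re_sd,
        ])

    @classmethod
    def from_fixed_vector(cls, vec, occ_random_effects=None, rep_random_effects=None):
        v = np.asarray(vec, dtype=float)
        return cls(
            occ_intercept=v[0], occ_beta_habitat=v[1], occ_beta_ecoregion=v[2],
            rep_intercept=v[3], rep_beta_habitat=v[4], rep_beta_ecoregion=v[5],
            det_intercepts=(v[6], v[8], v[10]), det_beta_habitat=(v[7], v[9], v[11]),
            occ_re_sd=v[12], rep_re_sd=v[13],
            occ_random_effects=occ_random_effects, rep_random_effects=rep_random_effects,
        )


def _linear_predictors(cov: SiteCovariates, params: ModelParameters):
    """Per-site logits (lpsi, lR, l22, l23, l33)."""
    if not cov.standardized:
        raise ValueError("covariates must be standardized before evaluating the model")
    x5 = cov.standardized_habitat5km
    x1 = cov.standardized_habitat1km
    sn = cov.ecoregion_indicator
    u_occ, u_rep = params.random_effects(cov.n_sites)
    lpsi = params.occ_intercept + u_occ + params.occ_beta_habitat * x5 \
        + params.occ_beta_ecoregion * sn
    lR = params.rep_intercept + u_rep + params.rep_beta_habitat * x5 \
        + params.rep_beta_ecoregion * sn
    a = params.det_intercepts
    b = params.det_beta_habitat
    return lpsi, lR, a[0] + b[0] * x1, a[1] + b[1] * x1, a[2] + b[2] * x1


def occupancy_and_reproduction(cov: SiteCovariates, params: ModelParameters,
                               site: int) -> tuple[float, float]:
    """(psi, R) for one site under the logit-linear submodels."""
    lpsi, lR, *_ = _linear_predictors(cov, params)
    return float(inv_logit(lpsi[site])), float(inv_logit(lR[site]))


def detection_probs(cov: SiteCovariates, params: ModelParameters,
                    site: int) -> tuple[float, float, float]:
    """(p22, p23, p33) for one site; logit-linear in 1-km habitat."""
    _, _, l22, l23, l33 = _linear_predictors(cov, params)
    return (float(inv_logit(l22[site])), float(inv_logit(l23[site])),
            float(inv_logit(l33[site])))


def site_year_marginal_loglik(y, phi, theta) -> float:
    """log Pr(history) for one site-year, marginalized over the latent state.

    ``y`` holds observed states with :data:`MISSING` (or NaN/None) marking
    inactive occasions; those contribute nothing.  An all-missing history has
    log-likelihood exactly 0.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    ys = [int(v) for v in np.asarray(y, dtype=object).ravel()
          if v is not None and not (isinstance(v, float) and np.isnan(v))
          and int(v) != MISSING]
    if not ys:
        return 0.0
    with np.errstate(divide="ignore"):
        log_theta = np.log(theta)
    per_state = np.array([sum(log_theta[z, yt] for yt in ys) for z in range(3)])
    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
    return float(logsumexp(log_phi + per_state))


@dataclass(frozen=True)
class SuffStats:
    """Per-site-year detection counts; everything the likelihood needs.

    Under the multinomial observation model the per-occasion ordering is
    irrelevant given z, so each site-year reduces to (active occasions,
    adult-only observations, cub observations).
    """

    site_idx: np.ndarray   # (n_sy,) site index of each site-year
    year_idx: np.ndarray   # (n_sy,)
    n_active: np.ndarray   # (n_sy,) active occasions
    n1: np.ndarray         # (n_sy,) occasions with y = 1
    n2: np.ndarray         # (n_sy,) occasions with y = 2

    @classmethod
    def from_history(cls, history: DetectionHistory) -> "SuffStats":
        n_sites, n_years, _ = history.observed_state.shape
        active = ~history.missing_mask
        n_active = active.sum(axis=2)
        n1 = ((history.observed_state == 1) & active).sum(axis=2)
        n2 = ((history.observed_state == 2) & active).sum(axis=2)
        s, yr = np.meshgrid(np.arange(n_sites), np.arange(n_years), indexing="ij")
        return cls(
            site_idx=s.ravel(), year_idx=yr.ravel(),
            n_active=n_active.ravel().astype(float),
            n1=n1.ravel().astype(float), n2=n2.ravel().astype(float),
        )

    @property
    def n_site_years(self) -> int:
        return self.site_idx.size


def state_logliks(stats: SuffStats, lpsi, lR, l22, l23, l33) -> np.ndarray:
    """(3, n_sy) array of log Pr(z) + log Pr(y | z) per site-year.

    Rows may be -inf where z is incompatible with the observations or where
    p23 + p33 >= 1 (constraint violation -> the z = 2 row and hence any
    history requiring it is impossible; callers treat an all -inf total as a
    rejection).
    """
    si = stats.site_idx
    n, n1, n2 = stats.n_active, stats.n1, stats.n2
    n0_z2 = n - n1 - n2
    log_psi, log_1mpsi = log_expit(lpsi)[si], log_expit(-lpsi)[si]
    log_R, log_1mR = log_expit(lR)[si], log_expit(-lR)[si]
    log_p22, log_1mp22 = log_expit(l22)[si], log_expit(-l22)[si]
    p23 = expit(l23)[si]
    p33 = expit(l33)[si]
    rest = 1.0 - p23 - p33
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p23 = np.log(p23)
        log_p33 = np.log(p33)
        log_rest = np.where(rest > 0, np.log(np.maximum(rest, 1e-300)), -np.inf)
    neg_inf = -np.inf
    lp0 = np.where(n1 + n2 > 0, neg_inf, log_1mpsi)
    lp1 = np.where(n2 > 0, neg_inf,
                   log_psi + log_1mR + n1 * log_p22 + (n - n1) * log_1mp22)
    with np.errstate(invalid="ignore"):
        obs2 = n1 * log_p23 + n2 * log_p33 + n0_z2 * log_rest
        # 0 * -inf (e.g. n2 = 0 with p33 = 0) must contribute 0, not NaN
        obs2 = np.where(
            np.isnan(obs2),
            np.where(n1, n1 * log_p23, 0.0)
            + np.where(n2, n2 * log_p33, 0.0)
            + np.where(n0_z2, n0_z2 * log_rest, 0.0),
            obs2,
        )
    lp2 = log_psi + log_R + obs2
    return np.vstack([lp0, lp1, lp2])


def total_loglik(data: DetectionHistory, cov: SiteCovariates,
                 params: ModelParameters) -> float:
    """Marginal log-likelihood summed over all site-years.

    Returns -inf when the detection constraint p23 + p33 <= 1 fails at any
    site (rejection semantics for MCMC proposals).
    """
    lpsi, lR, l22, l23, l33 = _linear_predictors(cov, params)
    if np.any(expit(l23) + expit(l33) > 1.0):
        return -np.inf
    stats = SuffStats.from_history(data)
    lp = state_logliks(stats, lpsi, lR, l22, l23, l33)
    return float(logsumexp(lp, axis=0).sum())


@dataclass(frozen=True)
class PriorSpec:
    """Diffuse priors: Normal(0, sd) on every fixed effect and detection
    coefficient, Uniform(0, upper) on the two random-effect sds."""

    fixed_effect_sd: float = 10.0
    re_sd_upper: float = 10.0


def log_prior(params: ModelParameters, prior: PriorSpec = PriorSpec()) -> float:
    """Joint log prior density, including Normal(0, sd) random-effect terms.

    -inf outside the support (non-positive sd or sd above the uniform
    bound)."""
    for sd in (params.occ_re_sd, params.rep_re_sd):
        if sd <= 0 or sd >= prior.re_sd_upper:
            return -np.inf
    fixed = params.fixed_vector()[:12]
    lp = float(norm.logpdf(fixed, scale=prior.fixed_effect_sd).sum())
    lp -= 2.0 * np.log(prior.re_sd_upper)  # the two uniform sd densities
    for re, sd in ((params.occ_random_effects, params.occ_re_sd),
                   (params.rep_random_effects, params.rep_re_sd)):
        if re is not None:
            lp += float(norm.logpdf(re, scale=sd).sum())
    return lp
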