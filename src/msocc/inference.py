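"""Posterior sampling for the multistate occupancy model.

The sampler is Metropolis-within-Gibbs with latent-state augmentation: each
iteration draws every site-year's latent state z from its exact full
conditional, then updates parameter blocks by random-walk Metropolis against
the complete-data log posterior.  Proposal scales adapt toward a target
acceptance rate during burn-in only, so the post-burn-in kernel is a fixed,
valid MCMC kernel.

Conditioned on z the likelihood factorizes into four independent pieces —
the state prior (psi), the conditional reproduction prior (R), the binomial
adult-detection piece (p22) and the trinomial cub-detection piece
(p23, p33) — each a function of per-site sufficient statistics, which keeps
every update a handful of vector operations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from .io import DetectionHistory, SiteCovariates
from .model import (
    FIXED_PARAM_NAMES, ModelParameters, PriorSpec, SuffStats,
    _linear_predictors, state_logliks,
)

__all__ = [
    "McmcConfig", "PosteriorDraws", "initialize_chains", "sample_latent_states",
    "update_parameters", "run_mcmc", "gelman_rubin", "summarize_posterior",
    "save_draws", "load_draws",
]

logger = logging.getLogger("msocc")

_RHAT_THRESHOLD = 1.1
_TARGET_ACCEPT = 0.35


@dataclass(frozen=True)
class McmcConfig:
    """MCMC protocol: chains, iterations, burn-in, thinning, adaptation.

    The defaults reproduce the study protocol: 3 chains of 200,000
    iterations, the first 100,000 discarded, thinning by 40, retaining 2,500
    draws per chain (7,500 total).
    """

    n_chains: int = 3
    n_iterations: int = 200_000
    burn_in: int = 100_000
    thin: int = 40
    seed: int = 0
    proposal_scales: dict | None = None  # block name -> initial scale
    adapt: bool = True

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iterations < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thin must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def n_retained_total(self) -> int:
        return self.n_retained_per_chain * self.n_chains


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, by chain.

    ``draws`` has shape (chain, retained draw, parameter); the first 14
    parameters are the fixed effects, detection coefficients and the two
    random-effect sds, followed (when sampled) by the per-site random
    effects.  ``latent_states`` optionally holds the sampled z per site-year.
    """

    draws: np.ndarray
    parameter_names: tuple
    latent_states: np.ndarray | None = None
    site_idx: np.ndarray | None = None
    year_idx: np.ndarray | None = None
    site_ids: tuple = ()
    year_labels: tuple = ()
    standardization_constants: dict | None = None
    config: McmcConfig | None = None
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.parameter_names = tuple(self.parameter_names)
        self._index = {n: i for i, n in enumerate(self.parameter_names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chain, retained draw)."""
        try:
            return self.draws[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (total draws,)."""
        return self.get(name).reshape(-1)

    def stacked_matrix(self, names) -> np.ndarray:
        """(total draws, len(names)) matrix of pooled draws."""
        cols = [self._index[n] for n in names]
        return self.draws[:, :, cols].reshape(-1, len(cols))


def _rhat(chains: np.ndarray) -> float:
    """Classic Gelman–Rubin potential scale reduction (no chain splitting)."""
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("Rhat needs at least 2 chains with at least 2 draws each")
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)  # = B / n
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_plus / within))


def gelman_rubin(draws: PosteriorDraws, parameter: str, split: bool = False) -> float:
    """Gelman–Rubin Rhat for one parameter; < 1.1 is taken as converged.

    ``split=True`` halves each chain first (the split-chain variant)."""
    chains = draws.get(parameter)
    if split:
        m, n = chains.shape
        half = n // 2
        chains = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    return _rhat(chains)


def summarize_posterior(draws: PosteriorDraws, parameters=None) -> pd.DataFrame:
    """Posterior mean, sd, 2.5/50/97.5 percentiles and Rhat per parameter.

    The ``converged`` flag marks parameters with Rhat < 1.1."""
    names = tuple(parameters) if parameters is not None else draws.parameter_names
    rows = []
    for name in names:
        x = draws.get(name)
        pooled = x.reshape(-1)
        lo, med, hi = np.percentile(pooled, [2.5, 50, 97.5])
        rhat = _rhat(x) if draws.n_chains >= 2 and x.shape[1] >= 2 else np.nan
        rows.append({
            "parameter": name, "mean": pooled.mean(), "sd": pooled.std(ddof=1),
            "q2.5": lo, "median": med, "q97.5": hi, "rhat": rhat,
            "converged": bool(rhat < _RHAT_THRESHOLD) if np.isfinite(rhat) else False,
        })
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Sampler internals

_COEF_BLOCKS = FIXED_PARAM_NAMES[:12]
_ALL_BLOCKS = _COEF_BLOCKS + ("occ_re", "rep_re", "occ_re_sd", "rep_re_sd")


class _Chain:
    """Mutable state of one MCMC chain over the sufficient statistics."""

    def __init__(self, data: DetectionHistory, cov: SiteCovariates,
                 prior: PriorSpec, rng: np.random.Generator,
                 init_params: ModelParameters | None,
                 include_random_effects: bool):
        self.stats = SuffStats.from_history(data)
        self.cov = cov
        self.prior = prior
        self.rng = rng
        self.n_sites = cov.n_sites
        self.x5 = cov.standardized_habitat5km
        self.x1 = cov.standardized_habitat1km
        self.sn = cov.ecoregion_indicator
        self.ones = np.ones(self.n_sites)
        self.include_re = include_random_effects
        # static per-site-year quantities reused every iteration
        st = self.stats
        self.si = st.site_idx
        self.n1 = st.n1
        self.n2 = st.n2
        self.nm1 = st.n_active - st.n1
        self.n0 = st.n_active - st.n1 - st.n2
        self.mask01 = (st.n1 + st.n2) > 0   # z = 0 impossible
        self.mask2 = st.n2 > 0              # z in {0, 1} impossible
        self.years_per_site = np.bincount(self.si, minlength=self.n_sites).astype(float)
        self._lp_buf = np.empty((3, st.n_site_years))
        if init_params is not None:
            params = init_params
            if include_random_effects and params.occ_random_effects is None:
                params = params.with_(
                    occ_random_effects=np.zeros(self.n_sites),
                    rep_random_effects=np.zeros(self.n_sites),
                )
        else:
            params = self._overdispersed_start()
        self.set_params(params)
        self.z = self._initial_latent_states()
        self._tally()
        self._check_finite_at_init()

    # -- initialization ----------------------------------------------------
    def _overdispersed_start(self) -> ModelParameters:
        rng = self.rng
        for _ in range(1000):
            vec = rng.normal(0.0, 1.5, size=12)
            sds = rng.uniform(0.25, min(3.0, self.prior.re_sd_upper), size=2)
            l23 = vec[8] + vec[9] * self.x1
            l33 = vec[10] + vec[11] * self.x1
            if np.any(expit(l23) + expit(l33) > 1.0):
                continue
            re_occ = rng.normal(0.0, sds[0], size=self.n_sites) if self.include_re else None
            re_rep = rng.normal(0.0, sds[1], size=self.n_sites) if self.include_re else None
            return ModelParameters.from_fixed_vector(
                np.concatenate([vec, sds]),
                occ_random_effects=re_occ, rep_random_effects=re_rep,
            )
        raise RuntimeError("could not find a valid overdispersed start "
                           "(detection constraint p23 + p33 <= 1)")

    def set_params(self, params: ModelParameters) -> None:
        self.vec = params.fixed_vector()
        re_occ, re_rep = params.random_effects(self.n_sites)
        self.re_occ = re_occ.copy()
        self.re_rep = re_rep.copy()
        lpsi, lR, l22, l23, l33 = _linear_predictors(self.cov, params)
        self.lpsi, self.lR = lpsi, lR
        self.l22, self.l23, self.l33 = l22, l23, l33

    def current_params(self) -> ModelParameters:
        return ModelParameters.from_fixed_vector(
            self.vec,
            occ_random_effects=self.re_occ.copy() if self.include_re else None,
            rep_random_effects=self.re_rep.copy() if self.include_re else None,
        )

    def _initial_latent_states(self) -> np.ndarray:
        """Max state ever observed; all-missing site-years draw from the prior."""
        st = self.stats
        z = np.zeros(st.n_site_years, dtype=np.int64)
        z[st.n1 > 0] = 1
        z[st.n2 > 0] = 2
        none_active = st.n_active == 0
        if none_active.any():
            psi = expit(self.lpsi)[st.site_idx[none_active]]
            R = expit(self.lR)[st.site_idx[none_active]]
            u = self.rng.random(none_active.sum())
            z[none_active] = np.where(u < 1 - psi, 0, np.where(u < 1 - psi * R, 1, 2))
        return z

    def _check_finite_at_init(self) -> None:
        parts = {
            "occupancy (psi) state prior": self.f_occ(self.lpsi),
            "reproduction (R) state prior": self.f_rep(self.lR),
            "adult detection (p22)": self.f_p22(self.l22),
            "cub-state detection (p23/p33)": self.f_p3(self.l23, self.l33),
        }
        for name, val in parts.items():
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite log-posterior at initialization in {name}"
                )

    # -- sufficient statistics given z ------------------------------------
    def _tally(self) -> None:
        n_sites, si = self.n_sites, self.si
        z1 = (self.z == 1).astype(float)
        z2 = (self.z == 2).astype(float)
        bc = lambda w: np.bincount(si, weights=w, minlength=n_sites)
        m1, m2 = bc(z1), bc(z2)
        self.m12 = m1 + m2
        self.m0 = self.years_per_site - self.m12
        self.mr1, self.mr2 = m1, m2
        self.a22 = bc(self.n1 * z1)
        self.b22 = bc(self.nm1 * z1)
        self.c23 = bc(self.n1 * z2)
        self.d33 = bc(self.n2 * z2)
        self.e3 = bc(self.n0 * z2)
        self.cur_f_occ = self.f_occ(self.lpsi)
        self.cur_f_rep = self.f_rep(self.lR)
        self.cur_f_p22 = self.f_p22(self.l22)
        self.cur_f_p3 = self.f_p3(self.l23, self.l33)

    # -- complete-data log-likelihood pieces -------------------------------
    def f_occ(self, lpsi):
        return self.m12 @ log_expit(lpsi) + self.m0 @ log_expit(-lpsi)

    def f_rep(self, lR):
        return self.mr2 @ log_expit(lR) + self.mr1 @ log_expit(-lR)

    def f_p22(self, l22):
        return self.a22 @ log_expit(l22) + self.b22 @ log_expit(-l22)

    def f_p3(self, l23, l33):
        p23, p33 = expit(l23), expit(l33)
        rest = 1.0 - p23 - p33
        if rest.min() <= 0.0:
            return -np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            # p23/p33 can underflow to exactly 0; a zero count must then
            # contribute 0 and a positive count -inf
            out = (self.c23 @ np.log(p23) + self.d33 @ np.log(p33)
                   + self.e3 @ np.log(rest))
        return out if not np.isnan(out) else -np.inf

    # -- Gibbs step for latent states --------------------------------------
    def draw_latent_states(self) -> None:
        """Exact draw of z per site-year; equivalent to sampling from
        state_logliks but specialized to valid in-sampler parameter states
        (the detection constraint holds, so every log is finite)."""
        si = self.si
        log_psi, log_1mpsi = log_expit(self.lpsi), log_expit(-self.lpsi)
        log_R, log_1mR = log_expit(self.lR), log_expit(-self.lR)
        log_p22, log_1mp22 = log_expit(self.l22), log_expit(-self.l22)
        p23, p33 = expit(self.l23), expit(self.l33)
        log_p23, log_p33 = np.log(p23), np.log(p33)
        log_rest = np.log(1.0 - p23 - p33)
        lp = self._lp_buf
        lp[0] = log_1mpsi[si]
        lp[0, self.mask01] = -np.inf
        lp[1] = (log_psi + log_1mR)[si] + self.n1 * log_p22[si] \
            + self.nm1 * log_1mp22[si]
        lp[1, self.mask2] = -np.inf
        lp[2] = (log_psi + log_R)[si] + self.n1 * log_p23[si] \
            + self.n2 * log_p33[si] + self.n0 * log_rest[si]
        lp += self.rng.gumbel(size=lp.shape)
        self.z = lp.argmax(axis=0)
        self._tally()

    def latent_state_conditional(self) -> np.ndarray:
        """Exact Pr(z | y, params) per site-year, shape (n_sy, 3)."""
        lp = state_logliks(self.stats, self.lpsi, self.lR,
                           self.l22, self.l23, self.l33)
        return np.exp(lp - logsumexp(lp, axis=0)).T

    def coef_descriptor(self, name: str):
        """(index, group, multiplier vector) for one coefficient block."""
        j = FIXED_PARAM_NAMES.index(name)
        group, term = name.split("_", 1)
        mult = {"intercept": self.ones, "habitat": self.x5, "ecoregion": self.sn}
        if group in ("p22", "p23", "p33"):
            mult["habitat"] = self.x1
        return j, group, mult[term]

    # -- Metropolis updates -------------------------------------------------
    def update_coef(self, desc, delta: float, log_u: float) -> bool:
        """One random-walk Metropolis step for a scalar coefficient.

        ``delta`` is the (already scaled) proposal increment and ``log_u``
        the log accept threshold; drawing them in one batch per iteration
        keeps the per-block overhead down."""
        j, group, m = desc
        new_val = self.vec[j] + delta
        dprior = -(new_val ** 2 - self.vec[j] ** 2) / (2 * self.prior.fixed_effect_sd ** 2)
        if group == "occ":
            lnew = self.lpsi + delta * m
            dll = self.f_occ(lnew) - self.cur_f_occ
        elif group == "rep":
            lnew = self.lR + delta * m
            dll = self.f_rep(lnew) - self.cur_f_rep
        elif group == "p22":
            lnew = self.l22 + delta * m
            dll = self.f_p22(lnew) - self.cur_f_p22
        elif group == "p23":
            lnew = self.l23 + delta * m
            dll = self.f_p3(lnew, self.l33) - self.cur_f_p3
        else:  # p33
            lnew = self.l33 + delta * m
            dll = self.f_p3(self.l23, lnew) - self.cur_f_p3
        if log_u < dll + dprior:
            self.vec[j] = new_val
            if group == "occ":
                self.lpsi = lnew
                self.cur_f_occ += dll
            elif group == "rep":
                self.lR = lnew
                self.cur_f_rep += dll
            elif group == "p22":
                self.l22 = lnew
                self.cur_f_p22 += dll
            elif group == "p23":
                self.l23 = lnew
                self.cur_f_p3 += dll
            else:
                self.l33 = lnew
                self.cur_f_p3 += dll
            return True
        return False

    def update_random_effects(self, which: str, scale: float) -> float:
        """Element-wise Metropolis on one random-effect vector.

        Sites are conditionally independent given z, so all accept/reject
        decisions happen in parallel.  Returns the acceptance fraction."""
        rng = self.rng
        eps = rng.normal(0.0, scale, size=self.n_sites)
        if which == "occ":
            re, sd, l = self.re_occ, self.vec[12], self.lpsi
            kpos, kneg = self.m12, self.m0
        else:
            re, sd, l = self.re_rep, self.vec[13], self.lR
            kpos, kneg = self.mr2, self.mr1
        lnew = l + eps
        d = (kpos * (log_expit(lnew) - log_expit(l))
             + kneg * (log_expit(-lnew) - log_expit(-l))
             - ((re + eps) ** 2 - re ** 2) / (2 * sd ** 2))
        accept = np.log(rng.random(self.n_sites)) < d
        re += eps * accept
        lkept = np.where(accept, lnew, l)
        if which == "occ":
            self.lpsi = lkept
            self.cur_f_occ = self.f_occ(lkept)
        else:
            self.lR = lkept
            self.cur_f_rep = self.f_rep(lkept)
        return np.count_nonzero(accept) / self.n_sites

    def update_re_sd(self, which: str, delta: float, log_u: float) -> bool:
        """Metropolis on log(sd) with the Uniform(0, upper) prior on sd."""
        j = 12 if which == "occ" else 13
        re = self.re_occ if which == "occ" else self.re_rep
        sd = self.vec[j]
        ls_new = np.log(sd) + delta
        sd_new = np.exp(ls_new)
        if sd_new >= self.prior.re_sd_upper:
            return False
        ssq = float(re @ re)
        d = (-self.n_sites * (ls_new - np.log(sd))
             - 0.5 * ssq * (sd_new ** -2 - sd ** -2)
             + (ls_new - np.log(sd)))  # Jacobian of the log transform
        if log_u < d:
            self.vec[j] = sd_new
            return True
        return False


def initialize_chains(data: DetectionHistory, cov: SiteCovariates,
                      config: McmcConfig, prior: PriorSpec = PriorSpec(),
                      init_params: ModelParameters | None = None,
                      include_random_effects: bool = True) -> list:
    """Seeded, overdispersed per-chain starting states.

    Latent states start at the maximum state ever observed at each site-year
    (the only assignment guaranteed compatible with the data); all-missing
    site-years draw z from the state prior.  Returns a list of internal chain
    states whose ``current_params()`` / ``z`` are the initial values."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    return [
        _Chain(data, cov, prior, np.random.Generator(np.random.PCG64(s)),
               init_params, include_random_effects)
        for s in seeds
    ]


def sample_latent_states(data: DetectionHistory, cov: SiteCovariates,
                         params: ModelParameters, rng: np.random.Generator
                         ) -> np.ndarray:
    """One exact draw of every site-year's latent state given parameters."""
    stats = SuffStats.from_history(data)
    lpsi, lR, l22, l23, l33 = _linear_predictors(cov, params)
    lp = state_logliks(stats, lpsi, lR, l22, l23, l33)
    g = rng.gumbel(size=lp.shape)
    return np.argmax(lp + g, axis=0)


def update_parameters(data: DetectionHistory, cov: SiteCovariates,
                      params: ModelParameters, z: np.ndarray,
                      config: McmcConfig, rng: np.random.Generator
                      ) -> ModelParameters:
    """One full Metropolis sweep over all parameter blocks, holding the
    latent states fixed at ``z``.

    Detail balance holds for each block against the complete-data posterior;
    proposals violating the detection constraint p23 + p33 <= 1 at any site
    are rejected outright.  Mainly useful for testing and for building
    custom samplers; :func:`run_mcmc` performs the full alternation."""
    chain = _Chain(data, cov, PriorSpec(), rng, params,
                   include_random_effects=True)
    chain.z = np.asarray(z, dtype=np.int64)
    chain._tally()
    user_scales = config.proposal_scales or {}
    for name in _COEF_BLOCKS:
        scale = float(user_scales.get(name, 0.1))
        chain.update_coef(chain.coef_descriptor(name),
                          rng.normal(0.0, scale), np.log(rng.random()))
    for which in ("occ", "rep"):
        chain.update_random_effects(which, float(user_scales.get(f"{which}_re", 0.1)))
        chain.update_re_sd(which, rng.normal(0.0, float(
            user_scales.get(f"{which}_re_sd", 0.1))), np.log(rng.random()))
    return chain.current_params()


def run_mcmc(data: DetectionHistory, cov: SiteCovariates, config: McmcConfig,
             prior: PriorSpec = PriorSpec(), *,
             update=None, init_params: ModelParameters | None = None,
             include_random_effects: bool = True,
             keep_latent_states: bool = True,
             progress: int | None = None) -> PosteriorDraws:
    """Run the full sampler and return thinned post-burn-in draws.

    Parameters
    ----------
    update : iterable of block names, optional
        Restrict sampling to these blocks (coefficient names plus
        ``occ_re``/``rep_re``/``occ_re_sd``/``rep_re_sd``); all other
        parameters stay fixed at their initial values.  Useful for
        conditional-posterior studies.
    init_params : ModelParameters, optional
        Common starting point for every chain instead of overdispersed
        random starts.
    include_random_effects : bool
        When False the site random effects are pinned at zero and their sds
        are not sampled (a fixed-effects-only model).
    """
    blocks = list(_ALL_BLOCKS if update is None else update)
    unknown = set(blocks) - set(_ALL_BLOCKS)
    if unknown:
        raise ValueError(f"unknown update blocks: {sorted(unknown)}")
    if not include_random_effects:
        blocks = [b for b in blocks if not b.startswith(("occ_re", "rep_re"))]

    chains = initialize_chains(data, cov, config, prior, init_params,
                               include_random_effects)
    n_keep = config.n_retained_per_chain
    n_sy = chains[0].stats.n_site_years
    re_names = ()
    if include_random_effects:
        re_names = tuple(f"occ_re[{s}]" for s in cov.site_ids) + \
                   tuple(f"rep_re[{s}]" for s in cov.site_ids)
    names = FIXED_PARAM_NAMES + re_names
    out = np.empty((config.n_chains, n_keep, len(names)))
    latents = (np.empty((config.n_chains, n_keep, n_sy), dtype=np.int8)
               if keep_latent_states else None)

    default_scale = 0.1
    user_scales = config.proposal_scales or {}
    for c, chain in enumerate(chains):
        scales = np.array([float(user_scales.get(b, default_scale)) for b in blocks])
        accepts = np.zeros(len(blocks))
        kinds = []  # (kind, payload) per block, in `blocks` order
        for b in blocks:
            if b in ("occ_re", "rep_re"):
                kinds.append(("re", b[:3]))
            elif b in ("occ_re_sd", "rep_re_sd"):
                kinds.append(("sd", b[:3]))
            else:
                kinds.append(("coef", chain.coef_descriptor(b)))
        nb = len(blocks)
        batch = 50
        n_batches = 0
        kept = 0
        for it in range(1, config.n_iterations + 1):
            chain.draw_latent_states()
            deltas = chain.rng.standard_normal(nb) * scales
            log_us = np.log(chain.rng.random(nb))
            for k in range(nb):
                kind, payload = kinds[k]
                if kind == "coef":
                    accepts[k] += chain.update_coef(payload, deltas[k], log_us[k])
                elif kind == "re":
                    accepts[k] += chain.update_random_effects(payload, scales[k])
                else:
                    accepts[k] += chain.update_re_sd(payload, deltas[k], log_us[k])
            if config.adapt and it <= config.burn_in and it % batch == 0:
                n_batches += 1
                step = min(0.25, 3.0 / np.sqrt(n_batches))
                scales *= np.exp(step * (accepts / batch - _TARGET_ACCEPT))
                accepts[:] = 0.0
            elif it == config.burn_in + 1:
                accepts[:] = 0.0
            if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
                row = chain.vec.copy()
                if include_random_effects:
                    row = np.concatenate([row, chain.re_occ, chain.re_rep])
                out[c, kept] = row
                if keep_latent_states:
                    latents[c, kept] = chain.z
                kept += 1
            if progress and it % progress == 0:
                logger.info("chain %d: iteration %d / %d", c + 1, it,
                            config.n_iterations)
        post_iters = config.n_iterations - config.burn_in
        if post_iters > 0:
            chain.post_burnin_acceptance = {
                b: accepts[k] / post_iters for k, b in enumerate(blocks)
            }
    draws = PosteriorDraws(
        draws=out, parameter_names=names, latent_states=latents,
        site_idx=chains[0].stats.site_idx, year_idx=chains[0].stats.year_idx,
        site_ids=cov.site_ids, year_labels=data.year_labels,
        standardization_constants=cov.standardization_constants,
        config=config,
    )
    draws.acceptance_rates = [getattr(c, "post_burnin_acceptance", {}) for c in chains]
    return draws


# ---------------------------------------------------------------------------
# Persistence (plain CSV + JSON sidecar)

def save_draws(draws: PosteriorDraws, directory) -> None:
    """Persist draws as CSV files with a JSON metadata sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n_chains, n_keep, _ = draws.draws.shape
    chain_col = np.repeat(np.arange(n_chains), n_keep)
    draw_col = np.tile(np.arange(n_keep), n_chains)
    flat = draws.draws.reshape(n_chains * n_keep, -1)
    df = pd.DataFrame(flat, columns=list(draws.parameter_names))
    df.insert(0, "draw", draw_col)
    df.insert(0, "chain", chain_col)
    df.to_csv(d / "draws.csv", index=False)
    if draws.latent_states is not None:
        lat = pd.DataFrame(
            draws.latent_states.reshape(n_chains * n_keep, -1),
            columns=[f"sy_{i}" for i in range(draws.latent_states.shape[2])],
        )
        lat.insert(0, "draw", draw_col)
        lat.insert(0, "chain", chain_col)
        lat.to_csv(d / "latent_states.csv", index=False)
    meta = {
        "site_ids": list(draws.site_ids),
        "year_labels": list(draws.year_labels),
        "site_idx": draws.site_idx.tolist() if draws.site_idx is not None else None,
        "year_idx": draws.year_idx.tolist() if draws.year_idx is not None else None,
        "standardization_constants": draws.standardization_constants,
        "config": asdict(draws.config) if draws.config else None,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_draws(directory) -> PosteriorDraws:
    """Inverse of :func:`save_draws`."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    df = pd.read_csv(d / "draws.csv")
    n_chains = int(df["chain"].max()) + 1
    n_keep = int(df["draw"].max()) + 1
    names = tuple(c for c in df.columns if c not in ("chain", "draw"))
    arr = df[list(names)].to_numpy().reshape(n_chains, n_keep, len(names))
    latents = None
    lat_path = d / "latent_states.csv"
    if lat_path.exists():
        lat = pd.read_csv(lat_path)
        cols = [c for c in lat.columns if c.startswith("sy_")]
        latents = lat[cols].to_numpy(dtype=np.int8).reshape(n_chains, n_keep, len(cols))
    config = McmcConfig(**meta["config"]) if meta.get("config") else None
    consts = meta.get("standardization_constants")
    if consts:
        consts = {k: tuple(v) for k, v in consts.items()}
    return PosteriorDraws(
        draws=arr, parameter_names=names, latent_states=latents,
        site_idx=np.asarray(meta["site_idx"]) if meta.get("site_idx") is not None else None,
        year_idx=np.asarray(meta["year_idx"]) if meta.get("year_idx") is not None else None,
        site_ids=tuple(meta.get("site_ids") or ()),
        year_labels=tuple(meta.get("year_labels") or ()),
        standardization_constants=consts,
        config=config,
    )
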