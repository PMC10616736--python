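"""Derived posterior quantities: covariate-response curves, covariate-grid
predictions, and finite-sample occupancy-state counts.

All prediction interfaces take *raw* habitat proportions in [0, 1]; they are
standardized internally with the constants stored at fit time, so "50%
habitat" means the same thing to the user and the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorDraws
from .io import ECOREGION_LEVELS

__all__ = ["PredictionRequest", "predict_psi_R", "predict_grid",
           "expected_state_counts"]

_GH_NODES = 21


def _marginal_expit(logits: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """E[expit(logit + u)] with u ~ Normal(0, sd^2), by Gauss-Hermite.

    ``logits`` is (draws, points); ``sd`` is (draws,) — the per-draw
    random-effect sd. Integrates the site random effect out of the response."""
    x, w = np.polynomial.hermite.hermgauss(_GH_NODES)
    u = np.sqrt(2.0) * x  # standard-normal nodes
    w = w / np.sqrt(np.pi)
    out = np.zeros_like(logits)
    for ui, wi in zip(u, w):
        out += wi * expit(logits + sd[:, None] * ui)
    return out


@dataclass(frozen=True)
class PredictionRequest:
    """Where to predict: raw habitat proportion(s), ecoregion level, and how
    to treat the site random effect (``typical`` pins it at 0, ``marginal``
    integrates over its fitted Normal(0, sd^2) distribution)."""

    habitat5km: object
    ecoregion: str = "GreatBasin"
    random_effect_policy: str = "typical"

    def __post_init__(self):
        if self.ecoregion not in ECOREGION_LEVELS:
            raise ValueError(f"unknown ecoregion {self.ecoregion!r}")
        if self.random_effect_policy not in ("typical", "marginal"):
            raise ValueError("random_effect_policy must be 'typical' or 'marginal'")
        h = np.atleast_1d(np.asarray(self.habitat5km, dtype=float))
        if np.any((h < 0) | (h > 1)):
            raise ValueError("habitat5km proportions must lie in [0, 1]")


def _per_draw_probs(draws: PosteriorDraws, habitat_raw, ecoregion, policy):
    """(psi, R) per pooled draw x prediction point, each (n_draws, n_points)."""
    h = np.atleast_1d(np.asarray(habitat_raw, dtype=float))
    mean, sd = draws.standardization_constants["habitat5km"]
    z = (h - mean) / sd
    sn = float(ECOREGION_LEVELS.index(ecoregion))
    occ = draws.stacked_matrix(["occ_intercept", "occ_habitat", "occ_ecoregion"])
    rep = draws.stacked_matrix(["rep_intercept", "rep_habitat", "rep_ecoregion"])
    lpsi = occ[:, [0]] + occ[:, [1]] * z[None, :] + occ[:, [2]] * sn
    lR = rep[:, [0]] + rep[:, [1]] * z[None, :] + rep[:, [2]] * sn
    if policy == "typical":
        return expit(lpsi), expit(lR)
    return (_marginal_expit(lpsi, draws.stacked("occ_re_sd")),
            _marginal_expit(lR, draws.stacked("rep_re_sd")))


def predict_psi_R(draws: PosteriorDraws, request: PredictionRequest) -> pd.DataFrame:
    """Posterior mean and central 95% interval of psi and R at requested
    covariates; one row per habitat value."""
    psi, R = _per_draw_probs(draws, request.habitat5km, request.ecoregion,
                             request.random_effect_policy)
    lo_psi, hi_psi = np.percentile(psi, [2.5, 97.5], axis=0)
    lo_R, hi_R = np.percentile(R, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "habitat5km": np.atleast_1d(np.asarray(request.habitat5km, dtype=float)),
        "ecoregion": request.ecoregion,
        "psi_mean": psi.mean(axis=0), "psi_lo": lo_psi, "psi_hi": hi_psi,
        "R_mean": R.mean(axis=0), "R_lo": lo_R, "R_hi": hi_R,
    })


def predict_grid(draws: PosteriorDraws, grid: pd.DataFrame,
                 random_effect_policy: str = "typical") -> pd.DataFrame:
    """Vectorized prediction over a table of (habitat5km, ecoregion) cells.

    Returns the input grid with per-cell posterior-mean psi and conditional R
    plus 95% intervals (map rendering is left to the caller)."""
    out = grid.reset_index(drop=True).copy()
    cols = ["psi_mean", "psi_lo", "psi_hi", "R_mean", "R_lo", "R_hi"]
    for c in cols:
        out[c] = np.nan
    for eco in out["ecoregion"].unique():
        rows = out.index[out["ecoregion"] == eco]
        pred = predict_psi_R(draws, PredictionRequest(
            habitat5km=out.loc[rows, "habitat5km"].to_numpy(),
            ecoregion=eco, random_effect_policy=random_effect_policy,
        ))
        out.loc[rows, cols] = pred[cols].to_numpy()
    return out


def expected_state_counts(draws: PosteriorDraws, year) -> pd.DataFrame:
    """Posterior mean and 95% interval of the number of sites per latent
    state in one year (plus the total occupied), tallied per retained draw.

    Requires latent states to have been retained during fitting."""
    if draws.latent_states is None:
        raise ValueError("latent states were not retained during fitting")
    year = str(year)
    labels = [str(y) for y in draws.year_labels]
    if year not in labels:
        raise KeyError(f"unknown year {year!r}; have {labels}")
    j = labels.index(year)
    mask = draws.year_idx == j
    lat = draws.latent_states[:, :, mask].reshape(-1, int(mask.sum()))
    counts = {
        "unoccupied": (lat == 0).sum(axis=1),
        "adults_only": (lat == 1).sum(axis=1),
        "with_cubs": (lat == 2).sum(axis=1),
    }
    counts["total_occupied"] = counts["adults_only"] + counts["with_cubs"]
    rows = []
    for state, n in counts.items():
        lo, hi = np.percentile(n, [2.5, 97.5])
        rows.append({"state": state, "year": year, "mean": n.mean(),
                     "q2.5": lo, "q97.5": hi})
    return pd.DataFrame(rows).set_index("state")
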