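import numpy as np
import pytest

import msocc


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated study shared across tests."""
    design = msocc.SimulationDesign(
        n_sites=25, n_sierra=4, n_years=2, n_occasions=5, seed=11,
    )
    history, cov, truth = msocc.simulate_study(design)
    return history, cov, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short (but converged enough for smoke checks) fit of the small study."""
    history, cov, _ = small_sim
    config = msocc.McmcConfig(
        n_chains=2, n_iterations=4000, burn_in=2000, thin=10, seed=5,
    )
    return msocc.run_mcmc(history, cov, config)


@pytest.fixture()
def tiny_fixture():
    """5 sites x 2 years x 3 occasions with handpicked states and missingness."""
    rng = np.random.default_rng(3)
    state = rng.integers(0, 3, size=(5, 2, 3)).astype(np.int8)
    mask = rng.random((5, 2, 3)) < 0.25
    mask[4, 1, :] = True  # one all-missing site-year
    history = msocc.DetectionHistory(state, mask)
    cov = msocc.SiteCovariates(
        site_ids=history.site_ids,
        habitat5km=np.array([0.1, 0.3, 0.5, 0.7, 0.9]),
        habitat1km=np.array([0.2, 0.25, 0.55, 0.6, 0.8]),
        ecoregion=("GreatBasin",) * 4 + ("SierraNevada",),
    )
    return history, cov


@pytest.fixture()
def example_params():
    return msocc.ModelParameters(
        occ_intercept=-0.4, occ_beta_habitat=1.2, occ_beta_ecoregion=2.0,
        rep_intercept=-0.8, rep_beta_habitat=0.9, rep_beta_ecoregion=1.1,
        det_intercepts=(-1.0, 0.2, -0.9), det_beta_habitat=(0.5, 0.0, -0.2),
        occ_re_sd=1.2, rep_re_sd=0.7,
        occ_random_effects=np.array([0.3, -0.2, 0.0, 0.5, -0.4]),
        rep_random_effects=np.array([-0.1, 0.2, 0.4, 0.0, -0.3]),
    )
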