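import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import kstest

import msocc
from msocc.io import MISSING
from msocc.inference import _rhat, initialize_chains
from msocc.model import state_probs

from oracles import enumerate_marginal, linear_predictors_naive, _ilogit


def _all_missing_history(n_sites=4, n_years=2, n_occasions=3):
    state = np.full((n_sites, n_years, n_occasions), MISSING, dtype=np.int8)
    return msocc.DetectionHistory(state, state == MISSING)


def _covariates(n_sites, rng):
    return msocc.SiteCovariates(
        tuple(f"s{i}" for i in range(n_sites)),
        rng.uniform(0.05, 0.95, n_sites), rng.uniform(0.05, 0.95, n_sites),
        ("GreatBasin",) * (n_sites - 1) + ("SierraNevada",),
    )


class TestMcmcConfig:
    def test_study_protocol_retains_2500_per_chain(self):
        config = msocc.McmcConfig()
        assert config.n_retained_per_chain == 2500
        assert config.n_retained_total == 7500

    def test_small_arithmetic(self):
        config = msocc.McmcConfig(n_chains=3, n_iterations=1000, burn_in=500,
                                  thin=10)
        assert config.n_retained_per_chain == 50
        assert config.n_retained_total == 150

    def test_invalid(self):
        with pytest.raises(ValueError):
            msocc.McmcConfig(burn_in=10, n_iterations=10)


class TestInitialization:
    def test_latent_start_is_max_observed_state(self, tiny_fixture):
        history, cov = tiny_fixture
        config = msocc.McmcConfig(n_chains=2, n_iterations=10, burn_in=5, seed=4)
        chains = initialize_chains(history, cov, config)
        stats = chains[0].stats
        for chain in chains:
            forced2 = stats.n2 > 0
            forced1 = (stats.n1 > 0) & ~forced2
            assert np.all(chain.z[forced2] == 2)
            assert np.all(chain.z[forced1] == 1)
            assert np.all((chain.z >= 0) & (chain.z <= 2))

    def test_same_seed_identical_starts(self, tiny_fixture):
        history, cov = tiny_fixture
        config = msocc.McmcConfig(n_chains=2, n_iterations=10, burn_in=5, seed=4)
        a, b = (initialize_chains(history, cov, config) for _ in range(2))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.vec, cb.vec)
            np.testing.assert_array_equal(ca.z, cb.z)

    def test_impossible_initial_likelihood_is_reported(self, tiny_fixture):
        history, cov = tiny_fixture  # contains observed cubs
        params = msocc.ModelParameters(det_intercepts=(0.0, 0.0, -800.0))
        config = msocc.McmcConfig(n_chains=1, n_iterations=10, burn_in=5)
        with pytest.raises(RuntimeError, match="cub-state detection"):
            initialize_chains(history, cov, config, init_params=params,
                              include_random_effects=False)


class TestLatentStates:
    def test_observed_cub_forces_state(self, tiny_fixture, example_params):
        history, cov = tiny_fixture
        stats = msocc.model.SuffStats.from_history(history)
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = msocc.sample_latent_states(history, cov, example_params, rng)
            assert np.all(z[stats.n2 > 0] == 2)
            assert np.all(z[stats.n1 > 0] >= 1)

    def test_empirical_frequencies_match_enumeration(self, example_params):
        """Sampled z frequencies agree with the enumerated full conditional
        within 3 Monte-Carlo standard errors on a fixed fixture."""
        state = np.array([[[0, 0, 1]], [[0, 0, 0]], [[MISSING] * 3]],
                         dtype=np.int8)
        history = msocc.DetectionHistory(state, state == MISSING)
        cov = msocc.SiteCovariates(history.site_ids, [0.2, 0.5, 0.8],
                                   [0.3, 0.5, 0.7], ("GreatBasin",) * 3)
        params = example_params.with_(
            occ_random_effects=np.zeros(3), rep_random_effects=np.zeros(3))
        # enumeration oracle for the conditional of each site-year
        expected = []
        for i in range(3):
            lpsi, lR, (l22, l23, l33) = linear_predictors_naive(cov, params, i)
            phi = state_probs(_ilogit(lpsi), _ilogit(lR))
            theta = msocc.observation_matrix(_ilogit(l22), _ilogit(l23),
                                             _ilogit(l33))
            y = [MISSING if history.missing_mask[i, 0, t]
                 else int(history.observed_state[i, 0, t]) for t in range(3)]
            joint = np.array([
                phi[z] * np.prod([theta[z, yt] for yt in y if yt != MISSING])
                for z in range(3)
            ])
            expected.append(joint / joint.sum())
        expected = np.array(expected)
        n = 20_000
        rng = np.random.default_rng(123)
        counts = np.zeros((3, 3))
        for _ in range(n):
            z = msocc.sample_latent_states(history, cov, params, rng)
            for sy, zz in enumerate(z):
                counts[sy, zz] += 1
        freq = counts / n
        se = np.sqrt(np.maximum(expected * (1 - expected), 1e-12) / n)
        assert np.all(np.abs(freq - expected) <= 3 * se + 1e-9)


class TestRunMcmc:
    def test_retained_draw_shapes(self, tiny_fixture):
        history, cov = tiny_fixture
        config = msocc.McmcConfig(n_chains=3, n_iterations=1000, burn_in=500,
                                  thin=10, seed=9)
        draws = msocc.run_mcmc(history, cov, config)
        assert draws.draws.shape[:2] == (3, 50)
        assert draws.draws.shape[0] * draws.draws.shape[1] == 150
        assert draws.latent_states.shape == (3, 50, 10)

    def test_bit_identical_given_seed(self, tiny_fixture):
        history, cov = tiny_fixture
        config = msocc.McmcConfig(n_chains=2, n_iterations=400, burn_in=200,
                                  thin=5, seed=21)
        a = msocc.run_mcmc(history, cov, config)
        b = msocc.run_mcmc(history, cov, config)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.latent_states, b.latent_states)

    def test_acceptance_rates_in_band(self, small_fit):
        """Burn-in adaptation should leave Metropolis acceptance in a healthy
        band on the packaged simulated fixture."""
        for chain_rates in small_fit.acceptance_rates:
            for block, rate in chain_rates.items():
                if block.endswith("_re"):
                    continue  # vector blocks report mean per-site acceptance
                assert 0.1 < rate < 0.6, (block, rate)

    def test_thinning_consistency(self, tiny_fixture):
        """Thinning more aggressively subsamples the same chain path, so
        summaries agree within Monte-Carlo error."""
        history, cov = tiny_fixture
        base = dict(n_chains=2, n_iterations=3000, burn_in=1000, seed=2)
        coarse = msocc.run_mcmc(history, cov, msocc.McmcConfig(thin=10, **base))
        fine = msocc.run_mcmc(history, cov, msocc.McmcConfig(thin=5, **base))
        for name in ("occ_intercept", "p22_intercept"):
            xc, xf = coarse.stacked(name), fine.stacked(name)
            tol = 4 * xf.std() / np.sqrt(len(xc) / 4)
            assert abs(xc.mean() - xf.mean()) < tol

    def test_prior_recovered_without_data(self):
        """With every occasion missing the posterior is the prior; KS test on
        fixed-effect draws against Normal(0, 10).  Checked on coefficients
        unaffected by the p23 + p33 <= 1 support truncation, in the
        fixed-effects-only model (random effects pinned at zero)."""
        history = _all_missing_history(n_sites=2, n_years=1, n_occasions=1)
        cov = msocc.SiteCovariates(history.site_ids, [0.2, 0.8], [0.3, 0.7],
                                   ("GreatBasin", "SierraNevada"))
        config = msocc.McmcConfig(n_chains=1, n_iterations=210_000,
                                  burn_in=10_000, thin=40, seed=17)
        draws = msocc.run_mcmc(history, cov, config, keep_latent_states=False,
                               include_random_effects=False)
        assert draws.n_draws_per_chain == 5000
        for name in ("occ_habitat", "p22_intercept", "rep_ecoregion"):
            stat = kstest(draws.stacked(name), "norm", args=(0, 10))
            assert stat.pvalue > 0.01, (name, stat)


class TestUpdateParameters:
    def test_single_sweep_valid_and_deterministic(self, tiny_fixture,
                                                  example_params):
        history, cov = tiny_fixture
        config = msocc.McmcConfig(n_chains=1, n_iterations=10, burn_in=5)
        z = msocc.sample_latent_states(history, cov, example_params,
                                       np.random.default_rng(1))
        out1 = msocc.update_parameters(history, cov, example_params, z, config,
                                       np.random.default_rng(2))
        out2 = msocc.update_parameters(history, cov, example_params, z, config,
                                       np.random.default_rng(2))
        np.testing.assert_array_equal(out1.fixed_vector(), out2.fixed_vector())
        # detection constraint respected at every site after the sweep
        from scipy.special import expit
        x1 = cov.standardized_habitat1km
        p23 = expit(out1.det_intercepts[1] + out1.det_beta_habitat[1] * x1)
        p33 = expit(out1.det_intercepts[2] + out1.det_beta_habitat[2] * x1)
        assert np.all(p23 + p33 <= 1.0)
        assert 0 < out1.occ_re_sd < 10

    def test_many_sweeps_move_parameters(self, tiny_fixture, example_params):
        history, cov = tiny_fixture
        config = msocc.McmcConfig(n_chains=1, n_iterations=10, burn_in=5)
        rng = np.random.default_rng(3)
        params = example_params
        for _ in range(20):
            z = msocc.sample_latent_states(history, cov, params, rng)
            params = msocc.update_parameters(history, cov, params, z, config, rng)
        assert not np.array_equal(params.fixed_vector(),
                                  example_params.fixed_vector())


class TestGelmanRubin:
    def _draws(self, chains):
        chains = np.asarray(chains, dtype=float)[:, :, None]
        return msocc.PosteriorDraws(chains, ("theta",))

    def test_identical_chains_closed_form(self):
        draws = self._draws([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert msocc.gelman_rubin(draws, "theta") == pytest.approx(
            np.sqrt(3 / 4), abs=1e-12)

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(1)
        draws = self._draws(rng.normal(size=(3, 10_000)))
        assert 0.99 < msocc.gelman_rubin(draws, "theta") < 1.02

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        draws = self._draws([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert msocc.gelman_rubin(draws, "theta") > 1.1

    def test_single_chain_rejected(self):
        draws = self._draws([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            msocc.gelman_rubin(draws, "theta")

    def test_chain_label_permutation_invariance(self, small_fit):
        permuted = msocc.PosteriorDraws(
            small_fit.draws[::-1].copy(), small_fit.parameter_names)
        for name in ("occ_intercept", "rep_habitat", "occ_re_sd"):
            assert msocc.gelman_rubin(small_fit, name) == pytest.approx(
                msocc.gelman_rubin(permuted, name), abs=1e-12)


class TestSummaries:
    def test_constant_parameter(self):
        arr = np.full((2, 50, 1), 3.25)
        draws = msocc.PosteriorDraws(arr, ("c",))
        row = msocc.summarize_posterior(draws).loc["c"]
        assert row["mean"] == 3.25 and row["q2.5"] == row["q97.5"] == 3.25

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(3)
        draws = msocc.PosteriorDraws(rng.normal(size=(2, 50_000, 1)), ("x",))
        row = msocc.summarize_posterior(draws).loc["x"]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.03)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.03)

    def test_one_row_per_parameter(self, small_fit):
        table = msocc.summarize_posterior(small_fit)
        assert len(table) == len(small_fit.parameter_names)


def test_save_load_roundtrip(small_fit, tmp_path):
    msocc.save_draws(small_fit, tmp_path / "draws")
    back = msocc.load_draws(tmp_path / "draws")
    np.testing.assert_allclose(back.draws, small_fit.draws, atol=1e-12)
    np.testing.assert_array_equal(back.latent_states, small_fit.latent_states)
    assert back.parameter_names == small_fit.parameter_names
    assert back.standardization_constants == small_fit.standardization_constants
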