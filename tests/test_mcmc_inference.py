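import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wetlandbirds.io_data import ModelSpec
from wetlandbirds.mcmc_inference import (
    ConfigError, MCMCConfig, PosteriorDraws, SPECIES_BURNIN, gelman_rubin,
    log_prior, logistic_log_pdf, run_chains, summarize,
)
from wetlandbirds.occupancy_model import Params

from conftest import make_intercept_only_study


def make_draws(chains, names=None):
    """PosteriorDraws from a (C, N, P) array of synthetic chains."""
    chains = np.asarray(chains, dtype=float)
    c, n, p = chains.shape
    names = names or [f"occ:b{i}" for i in range(p)]
    return PosteriorDraws(
        draws=chains.reshape(c * n, p),
        chain_id=np.repeat(np.arange(c), n),
        names=names, n_alpha=p)


class TestLogPrior:
    def test_logistic_density_at_zero(self):
        assert log_prior(Params([0.0], [])) == pytest.approx(np.log(0.25))

    def test_symmetry_and_additivity(self):
        x = np.array([0.3, -2.0, 5.5])
        assert log_prior(Params(x, [])) == pytest.approx(log_prior(Params(-x, [])))
        assert log_prior(Params(x, x)) == pytest.approx(
            2 * np.sum(logistic_log_pdf(x)))

    def test_matches_scipy_logistic(self):
        x = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(logistic_log_pdf(x),
                                   stats.logistic.logpdf(x), atol=1e-12)


class TestConfig:
    def test_burnin_must_be_smaller(self):
        with pytest.raises(ConfigError):
            MCMCConfig(n_iterations=100, n_burnin=100)

    def test_zero_retained_rejected(self):
        with pytest.raises(ConfigError):
            MCMCConfig(n_iterations=102, n_burnin=100, thin=5)

    @pytest.mark.parametrize("iters,burn,thin", [
        (100, 20, 1), (100, 20, 5), (101, 17, 7), (250, 249, 1),
    ])
    def test_retained_count_closed_form(self, iters, burn, thin):
        cfg = MCMCConfig(n_chains=2, n_iterations=iters, n_burnin=burn,
                         thin=thin, seed=0)
        assert cfg.n_retained_per_chain == (iters - burn) // thin

    def test_species_burnin_defaults(self):
        assert MCMCConfig.for_species("sosp").n_burnin == 5000
        assert MCMCConfig.for_species("deju").n_burnin == 2500
        assert SPECIES_BURNIN["swsp"] == 5000


class TestRunChains:
    def test_bookkeeping_on_real_run(self):
        det, sc, vc, _, design = make_intercept_only_study(30, 0.5, 0.5, seed=1)
        cfg = MCMCConfig(n_chains=3, n_iterations=203, n_burnin=50, thin=7,
                         seed=4)
        draws = run_chains(det, design, None, cfg)
        assert draws.n_draws == 3 * ((203 - 50) // 7)
        assert sorted(set(draws.chain_id)) == [0, 1, 2]
        assert np.isfinite(draws.draws).all()

    def test_same_seed_bit_identical(self):
        det, sc, vc, _, design = make_intercept_only_study(30, 0.5, 0.5, seed=1)
        cfg = MCMCConfig(n_chains=2, n_iterations=300, n_burnin=100, thin=2,
                         seed=11)
        a = run_chains(det, design, None, cfg)
        b = run_chains(det, design, None, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.chain_id, b.chain_id)

    def test_different_seeds_differ(self):
        det, sc, vc, _, design = make_intercept_only_study(30, 0.5, 0.5, seed=1)
        a = run_chains(det, design, None,
                       MCMCConfig(n_chains=1, n_iterations=300, n_burnin=100,
                                  seed=1))
        b = run_chains(det, design, None,
                       MCMCConfig(n_chains=1, n_iterations=300, n_burnin=100,
                                  seed=2))
        assert not np.array_equal(a.draws, b.draws)

    def test_acceptance_rates_recorded(self):
        det, sc, vc, _, design = make_intercept_only_study(40, 0.6, 0.6, seed=2)
        cfg = MCMCConfig(n_chains=2, n_iterations=600, n_burnin=300, seed=3)
        draws = run_chains(det, design, None, cfg)
        acc = draws.meta["acceptance"]
        assert acc.shape == (2, 2)
        assert ((acc > 0.05) & (acc < 0.95)).all()


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        draws = make_draws(rng.normal(size=(4, 5000, 2)))
        rhat = gelman_rubin(draws)
        assert (rhat < 1.01).all()
        # the classic estimator can dip a hair under 1 by sampling noise
        assert (rhat > 0.999).all()

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 1000, 1))
        chains[0] -= 5.0
        chains[1] += 5.0
        assert gelman_rubin(make_draws(chains)).iloc[0] > 1.1

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="two chains"):
            gelman_rubin(make_draws(rng.normal(size=(1, 100, 1))))

    def test_zero_variance_undefined(self):
        chains = np.ones((2, 100, 1))
        assert np.isnan(gelman_rubin(make_draws(chains)).iloc[0])


class TestSummarize:
    def test_quantile_rule_type7(self):
        draws = make_draws(np.array([[[1.0], [2.0], [3.0], [4.0], [5.0]]]))
        s = summarize(draws)
        # numpy linear-interpolation quantiles of (1..5)
        assert s["lo95"].iloc[0] == pytest.approx(np.quantile([1, 2, 3, 4, 5], 0.025))
        assert s["hi95"].iloc[0] == pytest.approx(4.9)
        assert s["lo50"].iloc[0] == pytest.approx(2.0)
        assert s["hi50"].iloc[0] == pytest.approx(4.0)
        assert s["median"].iloc[0] == 3.0

    def test_constant_draws_degenerate_intervals(self):
        s = summarize(make_draws(np.full((2, 50, 1), 3.14)))
        for col in ("lo50", "hi50", "lo95", "hi95", "mean", "median"):
            assert s[col].iloc[0] == pytest.approx(3.14)

    def test_intervals_nested(self):
        rng = np.random.default_rng(3)
        s = summarize(make_draws(rng.normal(size=(2, 500, 3))))
        assert (s["lo95"] <= s["lo50"]).all()
        assert (s["hi50"] <= s["hi95"]).all()

    def test_symmetric_draws_symmetric_intervals(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 4000, 1))
        x = np.concatenate([x, -x], axis=1)  # exactly symmetric about 0
        s = summarize(make_draws(x))
        assert s["lo50"].iloc[0] == pytest.approx(-s["hi50"].iloc[0], abs=1e-12)
        assert s["mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestPriorOnlySampling:
    def test_prior_marginal_is_logistic(self):
        """With the likelihood off, retained draws follow logistic(0, 1) and
        inv-logit(draws) is Uniform(0, 1)."""
        det, sc, vc, _, design = make_intercept_only_study(10, 0.5, 0.5, seed=5)
        cfg = MCMCConfig(n_chains=4, n_iterations=15_000, n_burnin=2_500,
                         thin=5, seed=20)
        draws = run_chains(det, design, None, cfg, prior_only=True)
        assert draws.n_draws == 4 * 2500
        x = draws.draws[:, 0]
        ks_logistic = stats.kstest(x, stats.logistic.cdf)
        assert ks_logistic.pvalue > 0.01
        u = 1.0 / (1.0 + np.exp(-x))
        assert stats.kstest(u, stats.uniform.cdf).pvalue > 0.01
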