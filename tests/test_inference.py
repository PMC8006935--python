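import math

import numpy as np
import pytest

from gliomasyn.inference import (
    DEFAULT_FREE_PARAMS,
    McmcChain,
    PriorSpec,
    chain_diagnostics,
    default_priors,
    dram_sample,
    effective_sample_size,
    geweke_z,
    log_likelihood,
    make_log_posterior,
    posterior_predictive,
    run_dram,
)
from gliomasyn.synthetic_data import generate_growth_data

FREE5 = ("alpha_C", "delta_C", "alpha_CR", "alpha_CS", "gamma_R")


@pytest.fixture(scope="module")
def noisefree_dataset(growth_params):
    return generate_growth_data(growth_params, noise_sd=0.0, seed=0)


@pytest.fixture(scope="module")
def short_chain(synthetic_dataset, growth_params):
    priors = default_priors(FREE5, base=growth_params)
    return run_dram(synthetic_dataset, priors, n_iter=3000, seed=11,
                    base=growth_params), priors


def truth_theta(growth_params, names):
    g = growth_params.to_dict()
    return np.array([g[n] for n in names])


class TestPriors:
    def test_default_priors_centred_at_defaults(self, growth_params):
        priors = default_priors(base=growth_params)
        assert priors.names == DEFAULT_FREE_PARAMS
        g = growth_params.to_dict()
        np.testing.assert_allclose(priors.means,
                                   [g[n] for n in DEFAULT_FREE_PARAMS])
        assert np.all(priors.lower < priors.means)
        assert np.all(priors.means < priors.upper)
        assert np.all(priors.upper <= np.where(
            np.isin(priors.names, ["gamma_R", "gamma_R_tilde",
                                   "omega_S_tilde"]), 1.0, np.inf))

    def test_log_density_bounds(self):
        priors = PriorSpec(("a",), np.array([1.0]), np.array([0.5]),
                           np.array([0.0]), np.array([2.0]))
        assert priors.log_density(np.array([1.0])) == 0.0
        assert priors.log_density(np.array([1.5])) == pytest.approx(-0.5)
        assert priors.log_density(np.array([2.5])) == -math.inf
        assert priors.log_density(np.array([-0.1])) == -math.inf

    def test_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(("a",), np.array([1.0]), np.array([0.0]),
                      np.array([0.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            PriorSpec(("a",), np.array([1.0]), np.array([0.5]),
                      np.array([2.0]), np.array([0.0]))


class TestLogLikelihood:
    def test_exact_normalization_at_truth(self, noisefree_dataset,
                                          growth_params):
        """Noise-free data at the true parameters leaves only the Gaussian
        normalization: -n log(sd) - n/2 log(2 pi) per compartment, up to the
        tiny fixed-step integrator error in the residuals."""
        theta = truth_theta(growth_params, FREE5)
        sd = 10.0
        ll = log_likelihood(theta, noisefree_dataset, noise_sd=sd,
                            free_names=FREE5)
        n = noisefree_dataset.times.size * 3
        expected = -n * math.log(sd) - 0.5 * n * math.log(2 * math.pi)
        assert ll == pytest.approx(expected, abs=0.01)

    def test_doubling_sd_shifts_by_n_log2(self, noisefree_dataset,
                                          growth_params):
        theta = truth_theta(growth_params, FREE5)
        ll1 = log_likelihood(theta, noisefree_dataset, noise_sd=10.0,
                             free_names=FREE5)
        ll2 = log_likelihood(theta, noisefree_dataset, noise_sd=20.0,
                             free_names=FREE5)
        n = noisefree_dataset.times.size * 3
        assert ll1 - ll2 == pytest.approx(n * math.log(2.0), abs=0.01)

    def test_truth_is_local_maximum(self, noisefree_dataset, growth_params):
        theta = truth_theta(growth_params, FREE5)
        ll0 = log_likelihood(theta, noisefree_dataset, noise_sd=10.0,
                             free_names=FREE5)
        for j in range(len(FREE5)):
            for fac in (0.9, 1.1):
                t = theta.copy()
                t[j] *= fac
                assert log_likelihood(t, noisefree_dataset, noise_sd=10.0,
                                      free_names=FREE5) < ll0

    def test_solver_blowup_gives_neg_inf(self, noisefree_dataset):
        assert log_likelihood(np.array([-5000.0]), noisefree_dataset,
                              noise_sd=10.0, free_names=("K",)) == -math.inf

    def test_shape_validation(self, noisefree_dataset):
        with pytest.raises(ValueError):
            log_likelihood(np.array([0.1, 0.2]), noisefree_dataset,
                           free_names=("alpha_C",))


class TestLogPosterior:
    def test_out_of_bounds_is_neg_inf(self, synthetic_dataset, growth_params):
        priors = default_priors(FREE5, base=growth_params)
        log_post = make_log_posterior(synthetic_dataset, priors,
                                      base=growth_params)
        assert log_post(priors.upper * 2.0) == -math.inf
        assert math.isfinite(log_post(priors.means))


class TestDramSampler:
    def test_bit_reproducible(self):
        log_post = lambda x: -0.5 * float(x @ x)
        x0, cov0 = np.zeros(2), np.eye(2)
        a = dram_sample(log_post, x0, cov0, n_iter=2000, seed=5)
        b = dram_sample(log_post, x0, cov0, n_iter=2000, seed=5)
        c = dram_sample(log_post, x0, cov0, n_iter=2000, seed=6)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate
        assert not np.array_equal(a.samples, c.samples)

    def test_samples_standard_gaussian(self):
        log_post = lambda x: -0.5 * float(x @ x)
        chain = dram_sample(log_post, np.zeros(2), 0.5 * np.eye(2),
                            n_iter=8000, seed=0)
        kept = chain.burned()
        assert np.abs(kept.mean(axis=0)).max() < 0.15
        assert np.abs(kept.std(axis=0) - 1.0).max() < 0.15

    def test_requires_min_iterations(self):
        with pytest.raises(ValueError):
            dram_sample(lambda x: 0.0, np.zeros(1), np.eye(1), n_iter=500)

    def test_rejects_bad_start(self):
        with pytest.raises(ValueError, match="non-finite"):
            dram_sample(lambda x: -math.inf, np.zeros(1), np.eye(1),
                        n_iter=1000)

    def test_delayed_rejection_raises_acceptance(self):
        log_post = lambda x: -0.5 * float(x @ x)
        # deliberately oversized proposal: DR's shrunk retry should recover
        # acceptances that plain Metropolis loses
        kw = dict(x0=np.zeros(3), cov0=25.0 * np.eye(3), n_iter=4000,
                  seed=2, adapt=False)
        with_dr = dram_sample(log_post, delayed_rejection=True, **kw)
        without = dram_sample(log_post, delayed_rejection=False, **kw)
        assert with_dr.acceptance_rate > without.acceptance_rate


class TestRunDram:
    def test_fit_moves_and_mixes(self, short_chain):
        chain, priors = short_chain
        assert 0.02 < chain.acceptance_rate < 0.9
        kept = chain.burned()
        assert np.all(np.ptp(kept, axis=0) > 0)
        assert chain.param_names == priors.names

    def test_chain_csv(self, short_chain, tmp_path):
        import pandas as pd
        chain, _ = short_chain
        path = tmp_path / "chain.csv"
        chain.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [*FREE5, "log_posterior"]
        assert len(df) == chain.n_iter


class TestDiagnostics:
    def test_ess_iid_vs_autocorrelated(self, rng):
        iid = rng.standard_normal(4000)
        ar = np.empty(4000)
        ar[0] = 0.0
        eps = rng.standard_normal(4000)
        for i in range(1, 4000):
            ar[i] = 0.95 * ar[i - 1] + eps[i]
        ess_iid = effective_sample_size(iid)
        ess_ar = effective_sample_size(ar)
        assert ess_iid > 2000
        assert ess_ar < 0.25 * ess_iid

    def test_ess_constant_is_nan(self):
        assert math.isnan(effective_sample_size(np.ones(100)))

    def test_geweke_iid_small(self, rng):
        z = geweke_z(rng.standard_normal(5000))
        assert abs(z) < 4.0

    def test_chain_diagnostics_frame(self):
        samples = np.column_stack([np.random.default_rng(0).normal(size=500),
                                   np.full(500, 3.0)])
        chain = McmcChain(samples=samples, log_posterior=np.zeros(500),
                          acceptance_rate=0.3, seed=0, n_iter=500,
                          param_names=("a", "b"))
        df = chain_diagnostics(chain)
        assert list(df["parameter"]) == ["a", "b"]
        assert not df.loc[0, "degenerate"]
        assert df.loc[1, "degenerate"]
        assert df.loc[1, "sd"] == 0.0
        assert df.loc[0, "q2.5"] < df.loc[0, "q50"] < df.loc[0, "q97.5"]


class TestPosteriorPredictive:
    def test_envelopes(self, short_chain, synthetic_dataset, growth_params):
        chain, _ = short_chain
        env = posterior_predictive(chain, synthetic_dataset, n_draws=100,
                                   base=growth_params, seed=0)
        for comp in synthetic_dataset.observed_compartments:
            lo, med, hi = env[comp]
            assert lo.shape == synthetic_dataset.times.shape
            assert np.all(lo <= med) and np.all(med <= hi)
            # predictive band should cover most observations of the
            # dataset the chain was fitted to
            obs = synthetic_dataset.observations[comp]
            frac = np.mean((obs >= lo) & (obs <= hi))
            assert frac >= 0.8

    def test_seeded_determinism(self, short_chain, synthetic_dataset,
                                growth_params):
        chain, _ = short_chain
        a = posterior_predictive(chain, synthetic_dataset, n_draws=50,
                                 base=growth_params, seed=4)
        b = posterior_predictive(chain, synthetic_dataset, n_draws=50,
                                 base=growth_params, seed=4)
        for comp in a:
            for x, y in zip(a[comp], b[comp]):
                np.testing.assert_array_equal(x, y)
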