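"""Sampler engine: single steps, chains, stationary laws, density oracles."""

import numpy as np
import pytest
from scipy import stats

from synsample.priors import GaussianMixturePrior, GaussianPrior
from synsample.sampler import (GradientModel, ParameterVector, SamplerConfig,
                               batch_step, discrete_step,
                               ensemble_stationary_samples,
                               fokker_planck_stationary_oracle,
                               reference_posterior_density, run_chain)


def _cfg(**kw):
    kw.setdefault("b", 1.0)
    kw.setdefault("dt", 1e-3)
    return SamplerConfig(**kw)


class TestDiscreteStep:
    def test_zero_gradients_zero_noise_is_identity(self):
        grads = GradientModel(prior_grad=np.zeros_like)
        th = np.array([0.3, -1.2, 2.0])
        out = discrete_step(th, grads, None, _cfg(), np.zeros(3))
        assert np.array_equal(out, th)

    def test_prior_mode_is_fixed_point_without_noise(self):
        # Gaussian prior mu=0.5, sigma=1: gradient vanishes at theta=0.5
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        out = discrete_step(np.array([0.5]), grads, None, _cfg(), np.zeros(1))
        assert out[0] == pytest.approx(0.5, abs=1e-15)

    def test_deterministic_given_noise(self):
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        noise = np.array([0.7, -1.1])
        th = np.array([0.0, 1.0])
        a = discrete_step(th, grads, None, _cfg(), noise)
        b = discrete_step(th, grads, None, _cfg(), noise)
        assert np.array_equal(a, b)

    def test_dimension_mismatch_fatal(self):
        grads = GradientModel(prior_grad=np.zeros_like)
        with pytest.raises(ValueError):
            discrete_step(np.zeros(3), grads, None, _cfg(), np.zeros(2))

    def test_nonfinite_gradient_fatal_with_index(self):
        def bad(th):
            g = np.zeros_like(th)
            g[1] = np.nan
            return g
        grads = GradientModel(prior_grad=bad)
        with pytest.raises(FloatingPointError, match="index 1"):
            discrete_step(np.zeros(3), grads, None, _cfg(), np.zeros(3))

    def test_parameter_vector_round_trip(self):
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        pv = ParameterVector(np.array([0.0, 1.0]))
        out = discrete_step(pv, grads, None, _cfg(), np.zeros(2))
        assert isinstance(out, ParameterVector)
        assert out.clip_low == pv.clip_low

    def test_gaussian_prior_chain_matches_analytic_moments(self):
        """Long prior-only chain at T=1 must sample Normal(mu, sigma^2)."""
        mu, sigma = 0.5, 1.0
        grads = GradientModel.from_prior(GaussianPrior(mu, sigma))
        traj = run_chain(np.array([mu]), grads, None,
                         _cfg(seed=7), n_steps=200_000, thin=1).ravel()
        # discard burn-in, thin to roughly independent samples
        # (OU relaxation time = sigma^2/(b dt) = 1000 steps)
        samples = traj[40_000::1000]
        n_eff = len(samples)
        assert abs(samples.mean() - mu) < 3 * sigma / np.sqrt(n_eff)
        assert abs(samples.var() - sigma**2) < 3 * sigma**2 * np.sqrt(2 / n_eff)


class TestBatchStep:
    @staticmethod
    def _grads():
        # Gaussian likelihood per observation: d/dtheta log N(x | theta, 1)
        return GradientModel(
            prior_grad=GaussianPrior(0.0, 1.0).grad_log_density,
            likelihood_grad=lambda th, x: x - th)

    def test_single_item_batch_equals_online_with_N1(self, rng):
        grads = self._grads()
        th = rng.normal(size=4)
        noise = rng.normal(size=4)
        a = batch_step(th, grads, [0.7], _cfg(), noise)
        b = discrete_step(th, grads, 0.7, _cfg(dataset_size_N=1), noise)
        assert np.allclose(a, b)

    def test_identical_inputs_batch_equals_online_drift(self, rng):
        """Batch over N identical inputs = online with the N multiplier."""
        grads = self._grads()
        th = rng.normal(size=3)
        noise = np.zeros(3)
        a = batch_step(th, grads, [0.7] * 5, _cfg(), noise)
        b = discrete_step(th, grads, 0.7, _cfg(dataset_size_N=5), noise)
        assert np.allclose(a, b)

    def test_empty_dataset_fatal(self):
        with pytest.raises(ValueError):
            batch_step(np.zeros(2), self._grads(), [], _cfg(), np.zeros(2))

    def test_online_approximates_batch_distribution(self):
        """For slow sampling the online chain cycling x^1..x^N reaches the
        same stationary distribution as the batch chain (KS < 0.05)."""
        data = [-0.4, 0.1, 0.9]
        grads = self._grads()
        cfg_b = _cfg(b=1.0, dt=1e-3, seed=3)
        rng = np.random.default_rng(11)
        n_chains, n_steps = 5000, 4000
        th_batch = rng.uniform(-2, 2, n_chains)
        th_online = th_batch.copy()
        cfg_o = _cfg(b=1.0, dt=1e-3 / len(data), dataset_size_N=len(data), seed=3)
        for step in range(n_steps):
            th_batch = batch_step(th_batch, grads, data, cfg_b,
                                  rng.standard_normal(n_chains))
            for x in data:  # one online sweep per batch step, matched time
                th_online = discrete_step(th_online, grads, x, cfg_o,
                                          rng.standard_normal(n_chains))
        ks = stats.ks_2samp(th_batch, th_online).statistic
        assert ks < 0.05


class TestRunChain:
    def test_single_step_trajectory(self):
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        traj = run_chain(np.zeros(2), grads, None, _cfg(seed=1), n_steps=1)
        assert traj.shape == (1, 2)

    def test_invalid_arguments(self):
        grads = GradientModel(prior_grad=np.zeros_like)
        with pytest.raises(ValueError):
            run_chain(np.zeros(1), grads, None, _cfg(), n_steps=0)
        with pytest.raises(ValueError):
            run_chain(np.zeros(1), grads, None, _cfg(), n_steps=5, thin=0)

    def test_same_seed_bit_identical(self):
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        a = run_chain(np.zeros(3), grads, None, _cfg(seed=9), n_steps=100)
        b = run_chain(np.zeros(3), grads, None, _cfg(seed=9), n_steps=100)
        assert np.array_equal(a, b)

    def test_thinning_subsamples_dense_trajectory(self):
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        dense = run_chain(np.zeros(2), grads, None, _cfg(seed=4), n_steps=100, thin=1)
        thinned = run_chain(np.zeros(2), grads, None, _cfg(seed=4), n_steps=100, thin=2)
        assert np.array_equal(thinned, dense[1::2])


class TestClamps:
    def test_clip_low_enforced(self):
        grads = GradientModel(prior_grad=lambda th: np.full_like(th, -1e9))
        out = discrete_step(np.zeros(2), grads, None,
                            _cfg(max_step=np.inf), np.zeros(2))
        assert np.all(out == -5.0)

    def test_max_step_enforced(self):
        grads = GradientModel(prior_grad=lambda th: np.full_like(th, 1e9))
        cfg = _cfg()  # default max_step = 5 b
        out = discrete_step(np.zeros(2), grads, None, cfg, np.zeros(2))
        assert np.all(out == 5.0 * cfg.b)

    def test_clamps_inert_on_test_posterior(self, rng):
        """With clip_low = -inf and max_step = inf the step equals the
        default-clamped step on a well-behaved posterior."""
        grads = GradientModel.from_prior(GaussianPrior(0.5, 1.0))
        th = rng.normal(0.5, 1.0, size=100)
        noise = rng.standard_normal(100)
        free = SamplerConfig(b=1.0, dt=1e-3, clip_low=-np.inf, max_step=np.inf)
        clamped = _cfg()
        assert np.array_equal(discrete_step(th, grads, None, free, noise),
                              discrete_step(th, grads, None, clamped, noise))


class TestReferenceDensities:
    def test_gaussian_prior_T1_is_normal(self):
        p = GaussianPrior(0.5, 1.0)
        grid = np.linspace(-6, 7, 4001)
        ref = reference_posterior_density(p.log_density, None, 1.0, grid)
        assert np.allclose(ref.density, stats.norm(0.5, 1.0).pdf(grid), atol=1e-8)
        assert ref.integral() == pytest.approx(1.0, abs=1e-6)

    def test_tempered_gaussian_variance_scales_with_T(self):
        # N(mu, s^2)^(1/T) is N(mu, T s^2): completing the square divides
        # the quadratic exponent by T
        p = GaussianPrior(0.5, 1.0)
        grid = np.linspace(-8, 9, 6001)
        ref = reference_posterior_density(p.log_density, None, 2.0, grid)
        assert np.allclose(ref.density, stats.norm(0.5, np.sqrt(2.0)).pdf(grid),
                           atol=1e-8)

    def test_conjugate_gaussian_posterior(self):
        # prior N(m0, s0^2) x likelihood N(x | theta, s^2) -> closed form
        m0, s0, x, s = 0.2, 1.5, 1.0, 0.5
        post_var = 1.0 / (1 / s0**2 + 1 / s**2)
        post_mean = post_var * (m0 / s0**2 + x / s**2)
        grid = np.linspace(-5, 6, 4001)
        ref = reference_posterior_density(
            GaussianPrior(m0, s0).log_density,
            lambda th: stats.norm(th, s).logpdf(x), 1.0, grid)
        assert np.allclose(ref.density,
                           stats.norm(post_mean, np.sqrt(post_var)).pdf(grid),
                           atol=1e-8)

    def test_narrow_grid_warns(self):
        p = GaussianPrior(0.0, 1.0)
        with pytest.warns(UserWarning, match="too narrow"):
            reference_posterior_density(p.log_density, None, 1.0,
                                        np.linspace(-1, 1, 101))


class TestFokkerPlanckOracle:
    def test_linear_drift_gives_normal(self):
        # A = b (mu - theta)/sigma^2, D = b T -> N(mu, T sigma^2)
        b, mu, sigma, T = 2.0, 0.5, 1.0, 1.5
        grid = np.linspace(-8, 9, 6001)
        ref = fokker_planck_stationary_oracle(
            lambda th: b * (mu - th) / sigma**2,
            lambda th: b * T * np.ones_like(th), grid)
        assert np.allclose(ref.density,
                           stats.norm(mu, sigma * np.sqrt(T)).pdf(grid), atol=1e-7)

    def test_double_well_matches_reference_density(self):
        """The zero-flux solution and direct exponentiation must agree on a
        bimodal posterior (total variation < 1e-6)."""
        mix = GaussianMixturePrior()
        lik_sd = 0.5
        grid = np.linspace(-1.5, 2.5, 4001)
        ref = reference_posterior_density(
            mix.log_density, lambda th: stats.norm(th, lik_sd).logpdf(0.5),
            1.0, grid)
        b = 1.0
        fp = fokker_planck_stationary_oracle(
            lambda th: b * (mix.grad_log_density(th) + (0.5 - th) / lik_sd**2),
            lambda th: b * np.ones_like(th), grid)
        assert ref.total_variation(fp) < 1e-6

    def test_halving_diffusion_halves_gaussian_variance(self):
        b, mu = 1.0, 0.0
        grid = np.linspace(-6, 6, 4001)
        full = fokker_planck_stationary_oracle(
            lambda th: b * (mu - th), lambda th: b * np.ones_like(th), grid)
        half = fokker_planck_stationary_oracle(
            lambda th: b * (mu - th), lambda th: 0.5 * b * np.ones_like(th), grid)
        assert half.var() == pytest.approx(0.5 * full.var(), rel=1e-4)

    def test_nonpositive_diffusion_fatal(self):
        with pytest.raises(ValueError):
            fokker_planck_stationary_oracle(
                lambda th: -th, lambda th: np.zeros_like(th),
                np.linspace(-1, 1, 11))


class TestStationaryLaws:
    """Long-run histograms of the discrete chain versus the analytic laws."""

    def test_stationarity_all_test_posteriors(self):
        """KS < 0.03 at 5e4 samples for each 1-D prior x likelihood pair."""
        cases = []
        p1 = GaussianPrior(0.5, 1.0)
        cases.append((GradientModel.from_prior(p1), p1.log_density, None,
                      (-2.0, 3.0), (-6, 7)))
        mix = GaussianMixturePrior()
        lik_sd = 0.5
        cases.append((GradientModel(
            prior_grad=lambda th: mix.grad_log_density(th) + (0.5 - th) / lik_sd**2),
            mix.log_density, lambda th: stats.norm(th, lik_sd).logpdf(0.5),
            (-0.5, 1.5), (-2, 3)))
        for i, (grads, logp, loglik, init, span) in enumerate(cases):
            cfg = SamplerConfig(b=1.0, dt=1e-3, seed=100 + i)
            # (the acceptance suite runs the 5e4-sample version; this
            # property test keeps the same tolerance at smaller n)
            samples = ensemble_stationary_samples(
                grads, cfg, n_samples=20_000, n_steps=16_000,
                init_low=init[0], init_high=init[1])
            grid = np.linspace(span[0], span[1], 4001)
            ref = reference_posterior_density(logp, loglik, 1.0, grid)
            assert ref.ks_statistic(samples) < 0.03

    def test_sampling_speed_invariance_requires_correction(self):
        """With b(theta)-modulation the T b'(theta) drift term keeps the
        stationary law invariant; omitting it measurably tilts it."""
        prior = GaussianPrior(0.5, 1.0)
        grads = GradientModel.from_prior(prior)
        b_fn = lambda th: 1.0 + 0.5 * np.tanh(th)
        b_prime = lambda th: 0.5 / np.cosh(th) ** 2

        cfg_c = SamplerConfig(b=b_fn, b_prime=b_prime, dt=1e-3, seed=5,
                              max_step=np.inf)
        corrected = ensemble_stationary_samples(grads, cfg_c, 15_000, 12_000,
                                                -2.0, 3.0)
        cfg_n = SamplerConfig(b=b_fn, b_prime=lambda th: np.zeros_like(th),
                              dt=1e-3, seed=5, max_step=np.inf)
        uncorrected = ensemble_stationary_samples(grads, cfg_n, 15_000, 12_000,
                                                  -2.0, 3.0)
        cfg_const = SamplerConfig(b=1.0, dt=1e-3, seed=6)
        const_b = ensemble_stationary_samples(grads, cfg_const, 15_000, 12_000,
                                              -2.0, 3.0)
        ks_corr = stats.ks_2samp(corrected, const_b).statistic
        ks_nc = stats.ks_2samp(uncorrected, const_b).statistic
        assert ks_corr < 0.03
        assert ks_nc > 2 * ks_corr
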