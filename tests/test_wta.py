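"""Spiking WTA circuit: kernels, rates, plasticity, simulation, analyses."""

import numpy as np
import pytest

from synsample.priors import GaussianPrior
from synsample.synthetic import bimodal_pattern_generator, rates_to_spikes
from synsample.recurrent import build_recurrent_network, lesion, simulate_pattern
from synsample.wta import (ALPHA_DEFAULT, MeanFieldWTA, NeuronModel,
                           SynapseMatrix, WTACircuit, epsp_kernel,
                           epsp_peak_time, firing_rates, peth,
                           reconstruct_stimulus, simulate,
                           stdp_likelihood_drift, stdp_sampling_update)


class TestEPSPKernel:
    def test_zero_before_and_at_onset(self):
        assert epsp_kernel(-1e-3) == 0.0
        assert epsp_kernel(0.0) == 0.0

    def test_peak_time_analytic(self):
        # tau_r tau_f/(tau_f - tau_r) ln(tau_f/tau_r) = (40/18) ms ln 10
        t_peak = epsp_peak_time()
        assert t_peak == pytest.approx(0.040 / 18 * np.log(10), rel=1e-12)
        s = np.linspace(0, 0.05, 100_001)
        assert s[np.argmax(epsp_kernel(s))] == pytest.approx(t_peak, abs=1e-6)

    def test_positive_after_onset(self):
        s = np.linspace(1e-4, 0.2, 100)
        assert np.all(epsp_kernel(s) > 0)


class TestFiringRates:
    def test_equal_potentials_split_evenly(self):
        rho = firing_rates(np.zeros(10))
        assert np.allclose(rho, 10.0)

    def test_total_rate_conserved_for_any_potentials(self, rng):
        for u in (rng.normal(0, 5, 10), np.array([1e4, 0.0, -1e4]),
                  np.full(7, -2000.0)):
            rho = firing_rates(u)
            assert np.sum(rho) == pytest.approx(100.0, abs=1e-9)
            assert np.all(rho >= 0)

    def test_winner_rate_value(self):
        u = np.zeros(10)
        u[0] = 5.0
        expected = 100.0 * np.exp(5) / (np.exp(5) + 9)
        assert firing_rates(u)[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(94.28, abs=0.01)


class TestSynapseMatrix:
    def test_weight_mapping_and_retraction_boundary(self):
        syn = SynapseMatrix(np.array([-2.0, 0.0, 1.0, 3.0]))
        w = syn.w
        assert np.all(np.diff(w) > 0)  # strictly increasing in theta
        # theta = 0 maps to w = e^-3 < 0.05, and w_eff exactly 0
        assert w[1] == pytest.approx(np.exp(-3.0))
        assert syn.w_eff[0] == 0.0 and syn.w_eff[1] == 0.0
        assert syn.w_eff[2] > 0

    def test_w_eff_zero_iff_nonfunctional(self, rng):
        theta = rng.uniform(-5, 4, 500)
        syn = SynapseMatrix(theta)
        assert np.array_equal(syn.w_eff > 0, theta > 0)

    def test_banned_synapse_silent(self):
        syn = SynapseMatrix(np.array([2.0, 2.0]), banned=np.array([True, False]))
        assert syn.w_eff[0] == 0.0 and syn.w_eff[1] > 0
        assert not syn.functional()[0]


class TestSTDPUpdate:
    def test_no_post_spike_reduces_to_prior_drift(self):
        prior = GaussianPrior(0.5, 1.0)
        theta = np.array([2.0])
        out = stdp_sampling_update(theta, 0, np.array([1.0]), prior,
                                   b=1e-4, N=100, dt=0.2, noise=np.zeros(1))
        expected = theta + 1e-4 * 0.2 * prior.grad_log_density(theta)
        assert np.allclose(out, expected)

    def test_likelihood_fixed_point(self):
        # x = alpha e^w at a post spike: the STDP bracket vanishes
        theta = np.array([3.5])
        w = np.exp(theta - 3.0)
        x = ALPHA_DEFAULT * np.exp(w)
        assert stdp_likelihood_drift(theta, x, b=1e-4, N=100) == pytest.approx(0.0)

    def test_retracted_synapse_drift_suppressed(self):
        """theta = -4 vs theta = 3 under identical strong activity: the
        likelihood drift is suppressed by the weight factor
        w(-4)/w(3) = e^-7, giving a ratio < 1e-3 (before clipping)."""
        x = np.array([5.0])
        d_retracted = stdp_likelihood_drift(np.array([-4.0]), x, b=1.0, N=100,
                                            max_step=np.inf)
        d_strong = stdp_likelihood_drift(np.array([3.0]), x, b=1.0, N=100,
                                         max_step=np.inf)
        assert abs(d_retracted[0] / d_strong[0]) < 1e-3

    def test_per_spike_clip_at_5b(self):
        d = stdp_likelihood_drift(np.array([3.0]), np.array([50.0]), b=1e-4, N=100)
        assert d[0] == pytest.approx(5e-4)

    def test_clip_low_enforced(self):
        out = stdp_sampling_update(np.array([-4.999]), 0, np.array([0.0]),
                                   GaussianPrior(0.5, 1.0), b=1.0, N=1, dt=1.0,
                                   noise=np.array([-100.0]))
        assert out[0] == -5.0


class TestSimulate:
    def test_no_input_rates_split_rho_net(self):
        """With silent afferents and zero weights each of the K neurons
        fires at rho_net / K (Poisson check over 100 s)."""
        circuit = WTACircuit(n_inputs=5, seed=0)
        circuit.synapses.theta[:] = -5.0  # all retracted
        out = simulate(circuit, np.empty((0, 2)), duration=100.0,
                       plasticity_on=False, rng=np.random.default_rng(1))
        counts = np.bincount(out["spikes"][:, 0].astype(int), minlength=10)
        expected = 100.0 / 10 * 100.0  # rate * duration
        assert np.all(np.abs(counts - expected) < 3 * np.sqrt(expected))

    def test_total_rate_conserved_every_step(self, rng):
        circuit = WTACircuit(n_inputs=20, seed=2)
        spikes = rates_to_spikes(np.full(20, 30.0), 2.0, rng)
        out = simulate(circuit, spikes, duration=2.0, plasticity_on=True,
                       rng=rng, record_every=1)
        sums = out["rho"].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_same_seed_identical_spike_trains(self, rng):
        spikes = rates_to_spikes(np.full(10, 20.0), 1.0, np.random.default_rng(3))
        outs = []
        for _ in range(2):
            circuit = WTACircuit(n_inputs=10, seed=5)
            outs.append(simulate(circuit, spikes, 1.0,
                                 rng=np.random.default_rng(7))["spikes"])
        assert np.array_equal(outs[0], outs[1])

    def test_adaptation_equalizes_rates(self):
        """The slow depressing current regulates per-neuron output rates:
        across-neuron spike-count variance drops when it is enabled."""
        rng0 = np.random.default_rng(0)
        spikes = rates_to_spikes(np.full(10, 40.0), 60.0, np.random.default_rng(9))
        variances = {}
        for adapt in (False, True):
            circuit = WTACircuit(n_inputs=10, seed=11)
            circuit.synapses.theta[:] = rng0.normal(1.5, 1.0, (10, 10))
            out = simulate(circuit, spikes, 60.0, plasticity_on=False,
                           adaptation_on=adapt, rng=np.random.default_rng(13))
            counts = np.bincount(out["spikes"][:, 0].astype(int), minlength=10)
            variances[adapt] = counts.var()
        assert variances[True] < variances[False]

    def test_plasticity_fixed_point_single_neuron(self):
        """1-neuron circuit, steady Poisson drive: the mean weight converges
        to log(x_bar / alpha), the zero of the deterministic drift."""
        nm = NeuronModel(K=1)
        circuit = WTACircuit(n_inputs=1, neuron=nm, seed=21)
        circuit.synapses.theta[:] = 1.0
        rate = 60.0
        x_bar = rate * (nm.tau_f - nm.tau_r)
        w_star = np.log(x_bar / ALPHA_DEFAULT)
        rng = np.random.default_rng(23)
        spikes = rates_to_spikes(np.array([rate]), 200.0, rng)
        w_trace = []
        # chunked simulation, tracking w over the last stretch
        for chunk in range(10):
            chunk_spikes = spikes[(spikes[:, 1] >= 20 * chunk)
                                  & (spikes[:, 1] < 20 * (chunk + 1))].copy()
            chunk_spikes[:, 1] -= 20 * chunk
            simulate(circuit, chunk_spikes, 20.0, plasticity_on=True, rng=rng)
            w_trace.append(circuit.synapses.w[0, 0])
        assert np.mean(w_trace[-3:]) == pytest.approx(w_star, abs=0.2)


class TestMeanFieldDriver:
    def test_reproducible_and_theta_clamped(self):
        from synsample.synthetic import ClusterWorld, TuningEnvironment
        env = TuningEnvironment(n_inputs=50, seed=1)
        world = ClusterWorld.standard(np.random.default_rng(2), 3)
        thetas = []
        for _ in range(2):
            m = MeanFieldWTA(n_inputs=50, seed=3)
            m.run_phase(env, world, 500, snapshot_interval=20.0)
            thetas.append(m.syn.theta.copy())
        assert np.array_equal(thetas[0], thetas[1])
        assert np.all(thetas[0] >= -5.0)


class TestRecurrentNetwork:
    def test_single_ensemble_reduces_to_feedforward(self):
        net = build_recurrent_network(n_inputs_A=20, n_ensembles=1,
                                      wta_per_ensemble=1, allow_lateral=False)
        assert net.n_hidden == 10
        assert net.functional_lateral_count() == 0
        assert "V" not in net.syn_ff

    def test_no_feedforward_crosses_modalities(self):
        net = build_recurrent_network(n_inputs_A=30, n_inputs_V=16, seed=1)
        mask = net.feedforward_allowed_mask()
        a_ids, v_ids = net.hidden_ids("A"), net.hidden_ids("V")
        assert not mask[np.ix_(a_ids, 30 + np.arange(16))].any()
        assert not mask[np.ix_(v_ids, np.arange(30))].any()

    def test_initial_functional_fraction_matches_prior_tail(self):
        """P(theta > 0) under Normal(0.5, 1) is Phi(0.5) ~ 0.69; the lateral
        matrix at initialization should match within 3 binomial SEs."""
        from scipy.stats import norm
        net = build_recurrent_network(n_inputs_A=40, n_inputs_V=25, seed=7)
        lat = net.syn_lat
        valid = ~np.eye(net.n_hidden, dtype=bool)
        frac = (lat.theta[valid] > 0).mean()
        p = norm.cdf(0.5)
        n = valid.sum()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_lesion_remove_all_lateral(self):
        net = build_recurrent_network(n_inputs_A=20, n_inputs_V=16, seed=2)
        lesion(net, "remove_lateral_synapses", net.syn_lat.functional())
        assert net.functional_lateral_count() == 0

    def test_banned_synapses_never_regrow(self):
        net = build_recurrent_network(n_inputs_A=20, n_inputs_V=16, seed=3)
        banned_mask = net.syn_lat.functional()
        lesion(net, "remove_lateral_synapses", banned_mask)
        rng = np.random.default_rng(4)
        for i in range(3):
            pat = bimodal_pattern_generator(i % 2, n_A=20, n_V=16, rng=rng)
            simulate_pattern(net, pat, rng, plasticity_on=True)
        assert not (net.syn_lat.functional() & banned_mask).any()
        assert np.all(net.syn_lat.w_eff[banned_mask] == 0.0)

    def test_remove_neurons_silences_and_disconnects(self):
        net = build_recurrent_network(n_inputs_A=20, n_inputs_V=16, seed=5)
        victims = net.hidden_ids("V")[:5]
        lesion(net, "remove_neurons", victims)
        assert net.removed[victims].all()
        assert np.all(net.syn_lat.w_eff[victims, :] == 0.0)
        assert np.all(net.syn_lat.w_eff[:, victims] == 0.0)
        rng = np.random.default_rng(6)
        pat = bimodal_pattern_generator(0, n_A=20, n_V=16, rng=rng)
        out = simulate_pattern(net, pat, rng, plasticity_on=False)
        fired = set(out["spikes"][:, 0].astype(int)) if len(out["spikes"]) else set()
        assert fired.isdisjoint(set(victims.tolist()))

    def test_unknown_neuron_id_fatal(self):
        net = build_recurrent_network(n_inputs_A=10, n_inputs_V=9, seed=8)
        with pytest.raises(KeyError):
            lesion(net, "remove_neurons", [999])
        with pytest.raises(ValueError):
            lesion(net, "remove_neurons", [])


class TestReconstruction:
    def test_zero_rates_zero_image(self):
        img = reconstruct_stimulus(np.ones((4, 9)), np.zeros(4))
        assert np.all(img == 0.0)

    def test_single_active_neuron_proportional(self, rng):
        eff = rng.uniform(0, 2, size=(4, 9))
        rates = np.array([0.0, 3.0, 0.0, 0.0])
        img = reconstruct_stimulus(eff, rates, normalize=False)
        assert np.allclose(img, 3.0 * eff[1])

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_stimulus(np.ones((2, 3)), np.array([1.0, -1.0]))


class TestPETH:
    def test_empty_trains_zero_matrix(self):
        out = peth([np.empty((0, 2))], n_neurons=3, t_max=0.5)
        assert np.all(out["matrix"] == 0.0)

    def test_single_spike_peak_bin(self):
        out = peth([np.array([[1, 0.100]])], n_neurons=3, t_max=0.5)
        assert out["argmax_bin"][1] == 10  # the 100 ms bin at 10 ms width

    def test_trial_summation_linear(self):
        trial = np.array([[0, 0.05], [1, 0.21], [0, 0.33]])
        one = peth([trial], n_neurons=2, t_max=0.5)
        two = peth([trial, trial], n_neurons=2, t_max=0.5)
        assert np.allclose(two["matrix"], 2.0 * one["matrix"])
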