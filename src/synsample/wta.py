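"""Spike-based winner-take-all circuit with synaptic sampling.

Network neurons are stochastic spike-response units: the membrane
potential is a weighted sum of normalized EPSP traces plus a slow
homeostatic adaptation current,

    u_k(t) = sum_i w_ki x_i(t) + beta_k(t),

and the instantaneous firing rate is exponential in u_k under idealized
divisive lateral inhibition, which makes the K rates a softmax with fixed
total output rate rho_net (100 Hz).  Spikes are drawn from Poisson
processes at these rates.

Each potential synapse carries a parameter theta; the efficacy is the
exponential mapping w = exp(theta - theta0) with offset theta0 = 3, and
the effective weight used by the membrane is w_eff = max(0, w - e^-theta0),
so theta <= 0 means a retracted, silent synapse (w < 0.05) that still
diffuses under the prior and noise and can regrow.  Plasticity follows
the synaptic sampling rule

    d theta = b [ (mu - theta)/sigma^2 + N w S(t) (x_i(t) - alpha e^w) ] dt
              + sqrt(2 b) dW,

a stochastic STDP rule: the data term acts only at postsynaptic spikes
(S(t)), with presynaptic activity read from the weight-normalized EPSP
trace x_i(t).  Defaults follow the reference parameterization
(b = 1e-4, N = 100, alpha = e^-2, prior mu = 0.5, sigma = 1).

Simulation is time-stepped (dt = 1 ms default) with exact per-step
exponential decay of both kernel components.  A mean-field pattern-level
driver (:class:`MeanFieldWTA`) replaces within-pattern spike timing by
stationary-trace expectations so that multi-hour learning schedules run
in minutes; it shares the plasticity arithmetic with the time-stepped
path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import logsumexp

from .priors import GaussianPrior

__all__ = [
    "NeuronModel",
    "epsp_kernel",
    "epsp_peak_time",
    "firing_rates",
    "SynapseMatrix",
    "stdp_likelihood_drift",
    "stdp_sampling_update",
    "WTACircuit",
    "simulate",
    "MeanFieldWTA",
    "reconstruct_stimulus",
    "peth",
]

THETA0_DEFAULT = 3.0
ALPHA_DEFAULT = float(np.exp(-2.0))


@dataclass
class NeuronModel:
    """Neuron and circuit constants of the WTA model."""

    K: int = 10                    # neurons per WTA circuit
    rho_net: float = 100.0         # total output rate (Hz)
    tau_r: float = 0.002           # EPSP rise (s)
    tau_f: float = 0.020           # EPSP fall (s)
    gamma: float = -8.0            # adaptation scale
    adapt_rise: float = 12.0       # adaptation kernel rise (s)
    adapt_fall: float = 30.0       # adaptation kernel fall (s)

    def __post_init__(self) -> None:
        if not (self.tau_f > self.tau_r > 0):
            raise ValueError("need tau_f > tau_r > 0")
        if self.rho_net <= 0:
            raise ValueError("rho_net must be > 0")


def epsp_kernel(s, tau_r: float = 0.002, tau_f: float = 0.020):
    """Double-exponential EPSP kernel eps(s) = H(s) (e^(-s/tau_f) - e^(-s/tau_r))."""
    s = np.asarray(s, dtype=float)
    out = np.where(s >= 0, np.exp(-s / tau_f) - np.exp(-s / tau_r), 0.0)
    return out if out.ndim else float(out)


def epsp_peak_time(tau_r: float = 0.002, tau_f: float = 0.020) -> float:
    """Argmax of the kernel: tau_r tau_f / (tau_f - tau_r) * ln(tau_f / tau_r)."""
    return tau_r * tau_f / (tau_f - tau_r) * np.log(tau_f / tau_r)


def firing_rates(u: np.ndarray, rho_net: float = 100.0) -> np.ndarray:
    """rho_k = rho_net exp(u_k) / sum_l exp(u_l), overflow-safe.

    The divisive inhibition makes the rates a softmax: the total rate is
    exactly rho_net for any membrane potentials.
    """
    u = np.asarray(u, dtype=float)
    m = np.max(u)
    e = np.exp(u - m)
    return rho_net * e / e.sum()


# ---------------------------------------------------------------------------
# synapse state and plasticity arithmetic

@dataclass
class SynapseMatrix:
    """Parameters theta of a bank of potential synapses plus the exponential
    theta -> w mapping and a regrowth-ban mask for lesion experiments."""

    theta: np.ndarray
    theta0: float = THETA0_DEFAULT
    alpha: float = ALPHA_DEFAULT
    delay: float = 0.0
    banned: np.ndarray | None = None  # excluded from updates, w_eff forced 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.banned is None:
            self.banned = np.zeros(self.theta.shape, dtype=bool)

    @property
    def w(self) -> np.ndarray:
        return np.exp(self.theta - self.theta0)

    @property
    def w_eff(self) -> np.ndarray:
        we = np.maximum(0.0, self.w - np.exp(-self.theta0))
        we[self.banned] = 0.0
        return we

    def functional(self) -> np.ndarray:
        return (self.theta > 0.0) & ~self.banned


def stdp_likelihood_drift(theta: np.ndarray, x: np.ndarray, b: float, N: int,
                          alpha: float = ALPHA_DEFAULT,
                          theta0: float = THETA0_DEFAULT,
                          max_step: float | None = None) -> np.ndarray:
    """Per-postsynaptic-spike likelihood increment b N w (x - alpha e^w),
    clipped to |.| <= 5b (the instantaneous-change clamp)."""
    w = np.exp(theta - theta0)
    d = b * N * w * (x - alpha * np.exp(w))
    clip = 5.0 * b if max_step is None else max_step
    return np.clip(d, -clip, clip)


def stdp_sampling_update(theta: np.ndarray, n_post_spikes, x, prior: GaussianPrior,
                         b: float, N: int, dt: float, noise: np.ndarray,
                         T: float = 1.0, alpha: float = ALPHA_DEFAULT,
                         theta0: float = THETA0_DEFAULT,
                         clip_low: float = -5.0) -> np.ndarray:
    """One synaptic sampling update over a window of length dt.

    ``n_post_spikes`` counts postsynaptic spikes in the window (the S(t)
    factor); the likelihood increment is applied per spike, the prior
    drift and the sqrt(2 T b dt) diffusion accumulate over the window.
    """
    theta = np.asarray(theta, dtype=float)
    dtheta = b * dt * prior.grad_log_density(theta)
    dtheta = dtheta + np.asarray(n_post_spikes) * stdp_likelihood_drift(
        theta, x, b, N, alpha, theta0)
    dtheta = dtheta + np.sqrt(2.0 * T * b * dt) * noise
    return np.maximum(theta + dtheta, clip_low)


# ---------------------------------------------------------------------------
# time-stepped simulation

class _DoubleExpTrace:
    """Difference-of-exponentials trace kept as two state vectors with exact
    per-step decay; a spike adds 1 to both components."""

    def __init__(self, n: int, tau_r: float, tau_f: float, dt: float):
        self.fall = np.zeros(n)
        self.rise = np.zeros(n)
        self.decay_f = np.exp(-dt / tau_f)
        self.decay_r = np.exp(-dt / tau_r)

    def step(self) -> None:
        self.fall *= self.decay_f
        self.rise *= self.decay_r

    def add(self, idx_or_vec) -> None:
        self.fall += idx_or_vec
        self.rise += idx_or_vec

    @property
    def value(self) -> np.ndarray:
        return self.fall - self.rise


@dataclass
class WTACircuit:
    """A single WTA circuit: K output neurons, n_inputs potential afferents."""

    n_inputs: int
    neuron: NeuronModel = field(default_factory=NeuronModel)
    prior: GaussianPrior = field(default_factory=lambda: GaussianPrior(0.5, 1.0))
    b: float = 1e-4
    N: int = 100
    synapses: SynapseMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synapses is None:
            rng = np.random.default_rng(self.seed)
            theta = self.prior.sample((self.neuron.K, self.n_inputs), rng)
            self.synapses = SynapseMatrix(theta)


def simulate(circuit: WTACircuit, input_spikes: np.ndarray, duration: float,
             dt: float = 1e-3, plasticity_on: bool = True,
             rng: np.random.Generator | None = None, noise_every: int = 50,
             record_every: int | None = None, adaptation_on: bool = True) -> dict:
    """Time-stepped simulation of one WTA circuit.

    ``input_spikes`` is an event array (neuron_id, time_s).  Per step the
    EPSP and adaptation traces decay exactly, membrane potentials and
    softmax rates are computed, output spikes are drawn as Bernoulli
    (rho_k dt), and — if plasticity is on — the likelihood term is applied
    at postsynaptic spikes while prior drift and diffusion accumulate in
    batches of ``noise_every`` steps (valid because the prior dynamics is
    orders of magnitude slower than dt).

    Returns output spikes, and optionally recorded potentials and rates.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    if rng is None:
        rng = np.random.default_rng(circuit.seed)
    nm = circuit.neuron
    syn = circuit.synapses
    n_steps = int(round(duration / dt))

    if nm.rho_net * dt > 0.2:
        warnings.warn("dt * max rate > 0.2: Poisson thinning is inaccurate",
                      stacklevel=2)

    ev = np.asarray(input_spikes, dtype=float).reshape(-1, 2)
    spike_step = np.minimum((ev[:, 1] / dt).astype(int), n_steps - 1) if len(ev) else \
        np.empty(0, dtype=int)
    order = np.argsort(spike_step, kind="stable")
    ev, spike_step = ev[order], spike_step[order]

    x_trace = _DoubleExpTrace(circuit.n_inputs, nm.tau_r, nm.tau_f, dt)
    # adaptation spans many calls (12 s / 30 s kernel): persist on circuit
    adapt = getattr(circuit, "_adapt", None)
    if adapt is None:
        adapt = _DoubleExpTrace(nm.K, nm.adapt_rise, nm.adapt_fall, dt)
        circuit._adapt = adapt

    out_spikes = []
    rec_u, rec_rho, rec_t = [], [], []
    ptr = 0
    steps_since_noise = 0
    for step in range(n_steps):
        x_trace.step()
        adapt.step()
        while ptr < len(ev) and spike_step[ptr] == step:
            x_trace.fall[int(ev[ptr, 0])] += 1.0
            x_trace.rise[int(ev[ptr, 0])] += 1.0
            ptr += 1

        x = x_trace.value
        beta = nm.gamma * adapt.value if adaptation_on else 0.0
        u = syn.w_eff @ x + beta
        rho = firing_rates(u, nm.rho_net)
        fired = rng.uniform(size=nm.K) < rho * dt
        t = (step + 1) * dt
        if np.any(fired):
            idx = np.nonzero(fired)[0]
            adapt.fall[idx] += 1.0
            adapt.rise[idx] += 1.0
            for k in idx:
                out_spikes.append((int(k), t))
            if plasticity_on:
                drift = stdp_likelihood_drift(syn.theta[idx], x[None, :],
                                              circuit.b, circuit.N,
                                              syn.alpha, syn.theta0)
                syn.theta[idx] = np.maximum(syn.theta[idx] + drift, -5.0)

        steps_since_noise += 1
        if plasticity_on and (steps_since_noise == noise_every or step == n_steps - 1):
            span = steps_since_noise * dt
            dtheta = circuit.b * span * circuit.prior.grad_log_density(syn.theta) \
                + np.sqrt(2.0 * circuit.b * span) * rng.standard_normal(syn.theta.shape)
            theta = np.maximum(syn.theta + dtheta, -5.0)
            theta[syn.banned] = syn.theta[syn.banned]
            syn.theta = theta
            steps_since_noise = 0

        if record_every and (step % record_every == 0):
            rec_t.append(t)
            rec_u.append(u.copy())
            rec_rho.append(rho.copy())

    result = {"spikes": np.asarray(out_spikes, dtype=float).reshape(-1, 2)}
    if record_every:
        u_arr = np.asarray(rec_u)
        result.update(time=np.asarray(rec_t), u=u_arr,
                      rho=np.asarray(rec_rho),
                      # divisive-inhibition term, stored in log space
                      log_I_lat=logsumexp(u_arr, axis=1))
    return result


# ---------------------------------------------------------------------------
# mean-field pattern-level driver

class MeanFieldWTA:
    """Pattern-level approximation of the WTA learning dynamics.

    Input rates are constant within each 200 ms pattern, so the
    weight-normalized EPSP trace of input i fluctuates around its
    stationary mean  x_bar_i = r_i (tau_f - tau_r).  The driver replaces
    the within-pattern spike-timing detail by this expectation: membrane
    potentials use x_bar, postsynaptic spike counts are Poisson
    (rho_k * duration), and the per-spike likelihood increment (clipped at
    5b per spike as in the event rule) is multiplied by the count.  Prior
    drift, diffusion and the adaptation current advance once per pattern.
    Because b = 1e-4 makes theta change by ~1e-3 per pattern, weights are
    additionally frozen over short blocks of patterns (default 5) to
    amortize the exp() evaluations.
    """

    def __init__(self, n_inputs: int = 1000, neuron: NeuronModel | None = None,
                 prior: GaussianPrior | None = None, b: float = 1e-4, N: int = 100,
                 seed: int = 0):
        self.neuron = neuron or NeuronModel()
        self.prior = prior or GaussianPrior(0.5, 1.0)
        self.b, self.N = b, N
        self.rng = np.random.default_rng(seed)
        theta = self.prior.sample((self.neuron.K, n_inputs), self.rng)
        self.syn = SynapseMatrix(theta)
        self.n_inputs = n_inputs
        # adaptation kernel states (per neuron)
        self._ad_fall = np.zeros(self.neuron.K)
        self._ad_rise = np.zeros(self.neuron.K)
        self.time = 0.0

    def copy(self) -> "MeanFieldWTA":
        import copy as _copy
        return _copy.deepcopy(self)

    def _present_block(self, xbars: np.ndarray, duration: float) -> None:
        """Advance the dynamics over a block of patterns with frozen weights."""
        nm, syn = self.neuron, self.syn
        w = syn.w
        w_eff = syn.w_eff
        ew = np.exp(w)
        d_lik = np.zeros_like(syn.theta)
        dec_f = np.exp(-duration / nm.adapt_fall)
        dec_r = np.exp(-duration / nm.adapt_rise)
        for xbar in xbars:
            beta = nm.gamma * (self._ad_fall - self._ad_rise)
            u = w_eff @ xbar + beta
            rho = firing_rates(u, nm.rho_net)
            n_post = self.rng.poisson(rho * duration)
            per_spike = np.clip(self.b * self.N * w * (xbar[None, :] - syn.alpha * ew),
                                -5.0 * self.b, 5.0 * self.b)
            d_lik += n_post[:, None] * per_spike
            self._ad_fall = self._ad_fall * dec_f + n_post
            self._ad_rise = self._ad_rise * dec_r + n_post
            self.time += duration
        span = duration * len(xbars)
        dtheta = d_lik + self.b * span * self.prior.grad_log_density(syn.theta) \
            + np.sqrt(2.0 * self.b * span) * self.rng.standard_normal(syn.theta.shape)
        theta = np.maximum(syn.theta + dtheta, -5.0)
        theta[syn.banned] = syn.theta[syn.banned]
        syn.theta = theta

    def run_phase(self, env, world, n_patterns: int, block_size: int = 5,
                  snapshot_interval: float = 1800.0,
                  snapshots: list | None = None) -> list:
        """Present ``n_patterns`` samples from ``world``; record theta > 0
        presence snapshots every ``snapshot_interval`` seconds."""
        from .synthetic import experience_to_rates, sample_world

        if snapshots is None:
            snapshots = []
        if not snapshots:
            snapshots.append((self.time, self.syn.functional().copy()))
        duration = env.pattern_duration
        trace_gain = self.neuron.tau_f - self.neuron.tau_r
        next_snap = snapshots[-1][0] + snapshot_interval
        done = 0
        while done < n_patterns:
            nb = min(block_size, n_patterns - done)
            points = sample_world(world, nb, self.rng)
            xbars = np.stack([experience_to_rates(env, p) for p in points]) * trace_gain
            self._present_block(xbars, duration)
            done += nb
            while self.time >= next_snap - 1e-9:
                snapshots.append((next_snap, self.syn.functional().copy()))
                next_snap += snapshot_interval
        return snapshots


# ---------------------------------------------------------------------------
# analysis helpers

def reconstruct_stimulus(efficacies: np.ndarray, rates: np.ndarray,
                         normalize: bool = True) -> np.ndarray:
    """Input-space image implied by hidden activity: the rate-weighted sum
    of the neurons' incoming efficacy vectors."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    img = rates @ np.asarray(efficacies, dtype=float)
    if normalize and img.max() > 0:
        img = img / img.max()
    return img


def peth(spike_trains: list, n_neurons: int, t_max: float,
         filter_sd: float = 0.050, bin_width: float = 0.010) -> dict:
    """Peri-event time histogram over aligned trials.

    ``spike_trains`` is a list of per-trial event arrays (neuron_id,
    time_s).  Spikes are summed over trials into ``bin_width`` bins and
    smoothed with a Gaussian filter of ``filter_sd`` along time.  Returns
    the matrix (neuron x bin), bin centers, and each neuron's argmax bin.
    """
    n_bins = int(np.ceil(t_max / bin_width))
    mat = np.zeros((n_neurons, n_bins))
    edges = np.arange(n_bins + 1) * bin_width
    for trial in spike_trains:
        trial = np.asarray(trial, dtype=float).reshape(-1, 2)
        for k in range(n_neurons):
            times = trial[trial[:, 0] == k, 1]
            if len(times):
                mat[k] += np.histogram(times, bins=edges)[0]
    smoothed = gaussian_filter1d(mat, sigma=filter_sd / bin_width, axis=1,
                                 mode="constant")
    return {"matrix": smoothed, "raw": mat,
            "bin_centers": edges[:-1] + bin_width / 2,
            "argmax_bin": np.argmax(smoothed, axis=1)}
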