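"""Recurrent multi-ensemble WTA network with lateral synapses and lesions.

Two ensembles of WTA circuits model multimodal association: "auditory"
hidden neurons z_A receive feedforward input only from auditory afferents
x_A, "visual" hidden neurons z_V only from x_V, while lateral excitatory
synapses among *all* hidden neurons are unconstrained (potentially
all-to-all, excluding self-connections) and carry a 5 ms transmission
delay.  Every synapse — feedforward and lateral — follows the same
synaptic sampling STDP rule with the Gaussian structural prior, so
connectivity is not fixed: connections retract, regrow and re-route.
Initial parameters are drawn from the prior.

Lesions come in two kinds: removing neurons (with all incident synapses),
and removing all currently functional lateral synapses while banning them
from regrowth.  Recovery after either lesion relies on the stochastic
exploration of the remaining potential connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import GaussianPrior
from .synthetic import BimodalPattern
from .wta import (ALPHA_DEFAULT, THETA0_DEFAULT, NeuronModel, SynapseMatrix,
                  _DoubleExpTrace, firing_rates, stdp_likelihood_drift)

__all__ = ["RecurrentNetwork", "build_recurrent_network", "lesion",
           "simulate_pattern"]


@dataclass
class RecurrentNetwork:
    neuron: NeuronModel
    prior: GaussianPrior
    b: float
    N: int
    n_inputs: dict            # {"A": n_A, "V": n_V}
    syn_ff: dict              # {"A": SynapseMatrix (n_A-side rows), "V": ...}
    syn_lat: SynapseMatrix    # (n_hidden, n_hidden), 5 ms delay
    wta_groups: np.ndarray    # (n_groups, K) global neuron ids
    ensemble_of: np.ndarray   # (n_hidden,) 0 = A, 1 = V
    removed: np.ndarray       # (n_hidden,) bool

    @property
    def n_hidden(self) -> int:
        return len(self.ensemble_of)

    def hidden_ids(self, modality: str) -> np.ndarray:
        return np.nonzero(self.ensemble_of == ("A", "V").index(modality))[0]

    def local_row(self, neuron_id: int) -> tuple[str, int]:
        """(modality, row index into that modality's feedforward matrix)."""
        mod = "A" if self.ensemble_of[neuron_id] == 0 else "V"
        return mod, int(self._local_of[neuron_id])

    def feedforward_allowed_mask(self) -> np.ndarray:
        """(n_hidden, n_A + n_V) mask of permitted feedforward synapses:
        block-diagonal by modality, so no synapse crosses modalities."""
        n_A, n_V = self.n_inputs["A"], self.n_inputs["V"]
        mask = np.zeros((self.n_hidden, n_A + n_V), dtype=bool)
        mask[np.ix_(self.hidden_ids("A"), np.arange(n_A))] = True
        mask[np.ix_(self.hidden_ids("V"), n_A + np.arange(n_V))] = True
        return mask

    def functional_lateral_count(self) -> int:
        return int(np.sum(self.syn_lat.functional()))


def build_recurrent_network(n_inputs_A: int = 100, n_inputs_V: int = 64,
                            n_ensembles: int = 2, wta_per_ensemble: int = 4,
                            K: int = 10, lateral_delay: float = 0.005,
                            allow_lateral: bool = True,
                            prior: GaussianPrior | None = None,
                            b: float = 1e-4, N: int = 100,
                            seed: int = 0) -> RecurrentNetwork:
    """Assemble the network; theta drawn independently from the prior.

    With ``n_ensembles=1`` and ``allow_lateral=False`` this reduces to the
    single feedforward WTA architecture.
    """
    prior = prior or GaussianPrior(0.5, 1.0)
    rng = np.random.default_rng(seed)
    neuron = NeuronModel(K=K)
    n_hidden = n_ensembles * wta_per_ensemble * K
    half = n_hidden // n_ensembles if n_ensembles > 1 else n_hidden
    ensemble_of = np.zeros(n_hidden, dtype=int)
    if n_ensembles > 1:
        ensemble_of[half:] = 1
    groups = np.arange(n_hidden).reshape(-1, K)

    syn_ff = {"A": SynapseMatrix(prior.sample((half, n_inputs_A), rng))}
    if n_ensembles > 1:
        syn_ff["V"] = SynapseMatrix(prior.sample((n_hidden - half, n_inputs_V), rng))
    lat = SynapseMatrix(prior.sample((n_hidden, n_hidden), rng), delay=lateral_delay)
    np.fill_diagonal(lat.banned, True)  # no self-synapses
    np.fill_diagonal(lat.theta, -5.0)
    if not allow_lateral:
        lat.banned[:] = True
        lat.theta[:] = -5.0
    net = RecurrentNetwork(
        neuron=neuron, prior=prior, b=b, N=N,
        n_inputs={"A": n_inputs_A, "V": n_inputs_V if n_ensembles > 1 else 0},
        syn_ff=syn_ff, syn_lat=lat, wta_groups=groups,
        ensemble_of=ensemble_of, removed=np.zeros(n_hidden, dtype=bool))
    local = np.zeros(n_hidden, dtype=int)
    local[ensemble_of == 0] = np.arange(int(np.sum(ensemble_of == 0)))
    local[ensemble_of == 1] = np.arange(int(np.sum(ensemble_of == 1)))
    net._local_of = local
    return net


def lesion(net: RecurrentNetwork, kind: str, selection) -> RecurrentNetwork:
    """Apply a lesion in place and return the network.

    ``remove_neurons``: the selected hidden neurons are silenced forever
    and all their incident synapses (feedforward and lateral, both
    directions) are retracted and banned.  ``remove_lateral_synapses``:
    the selected lateral (pre, post) pairs are retracted and banned from
    regrowth — they are excluded from all future updates, so their
    effective weight stays zero.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("lesion selection must be non-empty")
    net._fast_stale = True  # compiled driver must reload theta/masks
    if kind == "remove_neurons":
        ids = selection.astype(int)
        if np.any(ids < 0) or np.any(ids >= net.n_hidden):
            raise KeyError(f"unknown neuron ids in {ids}")
        net.removed[ids] = True
        net.syn_lat.theta[ids, :] = -5.0
        net.syn_lat.theta[:, ids] = -5.0
        net.syn_lat.banned[ids, :] = True
        net.syn_lat.banned[:, ids] = True
        for mod in net.syn_ff:
            local = _local_rows(net, mod, ids)
            net.syn_ff[mod].theta[local, :] = -5.0
            net.syn_ff[mod].banned[local, :] = True
    elif kind == "remove_lateral_synapses":
        if selection.dtype == bool:
            mask = selection
        else:
            mask = np.zeros(net.syn_lat.theta.shape, dtype=bool)
            mask[tuple(selection.T)] = True
        net.syn_lat.theta[mask] = -5.0
        net.syn_lat.banned |= mask
    else:
        raise ValueError(f"unknown lesion kind {kind!r}")
    return net


def _local_rows(net: RecurrentNetwork, modality: str, global_ids) -> np.ndarray:
    ids = np.atleast_1d(np.asarray(global_ids, dtype=int))
    want = ("A", "V").index(modality)
    return net._local_of[ids[net.ensemble_of[ids] == want]]


def simulate_pattern(net: RecurrentNetwork, pattern: BimodalPattern,
                     rng: np.random.Generator, plasticity_on: bool = True,
                     audio_only: bool = False, pad: float = 0.025,
                     pad_rate: float = 1.0, dt: float = 1e-3) -> dict:
    """Present one bimodal pattern (with 25 ms 1 Hz padding) to the network.

    In audio-only probe trials the visual afferents stay at 1 Hz for the
    whole presentation (``audio_only=True``); probes are normally run with
    plasticity off (learning rate set to zero).  Returns the hidden spike
    events, per-neuron spike counts, and mean z_V rates over the pattern
    window (the readout features).
    """
    nm = net.neuron
    n_A, n_V = net.n_inputs["A"], net.n_inputs["V"]
    ids_A, ids_V = net.hidden_ids("A"), net.hidden_ids("V")
    duration = pattern.duration
    n_steps = int(round((duration + 2 * pad) / dt))
    pat_lo, pat_hi = pad, pad + duration

    xA = _DoubleExpTrace(n_A, nm.tau_r, nm.tau_f, dt)
    xV = _DoubleExpTrace(n_V, nm.tau_r, nm.tau_f, dt)
    xL = _DoubleExpTrace(net.n_hidden, nm.tau_r, nm.tau_f, dt)
    # the homeostatic current spans many presentations (12 s / 30 s
    # kernel): its state persists on the network across calls
    adapt = getattr(net, "_adapt", None)
    if adapt is None or adapt.fall.shape[0] != net.n_hidden:
        adapt = _DoubleExpTrace(net.n_hidden, nm.adapt_rise, nm.adapt_fall, dt)
        net._adapt = adapt
    delay_steps = max(int(round(net.syn_lat.delay / dt)), 1)
    spike_ring = np.zeros((delay_steps, net.n_hidden))

    wA = net.syn_ff["A"].w_eff
    wV = net.syn_ff["V"].w_eff if "V" in net.syn_ff else None
    wL = net.syn_lat.w_eff
    alive = ~net.removed
    K = net.wta_groups.shape[1]

    # pre-draw all input spikes and hidden thresholds for the pattern
    t_axis = np.arange(n_steps) * dt
    in_pat = (t_axis >= pat_lo) & (t_axis < pat_hi)
    ratesA = np.full((n_steps, n_A), pad_rate)
    frames = np.minimum(((t_axis[in_pat] - pat_lo) / pattern.frame_dt).astype(int),
                        pattern.rates_A.shape[0] - 1)
    ratesA[in_pat] = pattern.rates_A[frames]
    ratesV = np.full((n_steps, n_V), pad_rate)
    if not audio_only:
        ratesV[in_pat] = pattern.rates_V
    in_spikes_A = rng.random((n_steps, n_A)) < ratesA * dt
    in_spikes_V = rng.random((n_steps, n_V)) < ratesV * dt
    thresholds = rng.random((n_steps, net.n_hidden))
    u_dead = np.where(alive, 0.0, -np.inf)  # removed: out of the softmax

    spikes, counts = [], np.zeros(net.n_hidden)
    window_counts = np.zeros(net.n_hidden)
    for step in range(n_steps):
        t = step * dt
        in_pattern = in_pat[step]
        xA.step(); xV.step(); xL.step(); adapt.step()
        xA.add(in_spikes_A[step])
        xV.add(in_spikes_V[step])
        xL.add(spike_ring[step % delay_steps])

        u = np.empty(net.n_hidden)
        u[ids_A] = wA @ xA.value
        if wV is not None:
            u[ids_V] = wV @ xV.value
        u += wL @ xL.value + nm.gamma * adapt.value + u_dead

        # vectorized per-WTA softmax: each group's rates sum to rho_net
        ug = u.reshape(-1, K)
        m = ug.max(axis=1, keepdims=True)
        m[~np.isfinite(m)] = 0.0  # fully-removed group
        e = np.exp(ug - m)
        denom = e.sum(axis=1, keepdims=True)
        rho = (nm.rho_net * e / np.maximum(denom, 1e-300)).ravel()
        rho[~alive] = 0.0
        fired = (thresholds[step] < rho * dt) & alive
        spike_ring[step % delay_steps] = fired.astype(float)
        if np.any(fired):
            idx = np.nonzero(fired)[0]
            adapt.fall[idx] += 1.0
            adapt.rise[idx] += 1.0
            counts[idx] += 1
            if in_pattern:
                window_counts[idx] += 1
            for k in idx:
                spikes.append((int(k), t))
            if plasticity_on:
                _apply_post_spike_plasticity(net, idx, xA.value, xV.value, xL.value)
                # refresh only the efficacy rows the spikes touched
                for k in idx:
                    mod, r = net.local_row(k)
                    if mod == "A":
                        wA[r] = _row_w_eff(net.syn_ff["A"], r)
                    elif wV is not None:
                        wV[r] = _row_w_eff(net.syn_ff["V"], r)
                    wL[k] = _row_w_eff(net.syn_lat, k)

    if plasticity_on:
        _apply_prior_diffusion(net, n_steps * dt, rng)

    rates_V = window_counts[ids_V] / duration
    return {"spikes": np.asarray(spikes, dtype=float).reshape(-1, 2),
            "counts": counts, "rates_V": rates_V, "t_max": n_steps * dt}


def _row_w_eff(syn: SynapseMatrix, r: int) -> np.ndarray:
    we = np.maximum(0.0, np.exp(syn.theta[r] - syn.theta0) - np.exp(-syn.theta0))
    we[syn.banned[r]] = 0.0
    return we


def _apply_post_spike_plasticity(net, idx, xA, xV, xL) -> None:
    for k in idx:
        mod, r = net.local_row(k)
        if mod in net.syn_ff:
            syn = net.syn_ff[mod]
            x = xA if mod == "A" else xV
            d = stdp_likelihood_drift(syn.theta[r], x, net.b, net.N,
                                      syn.alpha, syn.theta0)
            d[syn.banned[r]] = 0.0
            syn.theta[r] = np.maximum(syn.theta[r] + d, -5.0)
        lat = net.syn_lat
        d = stdp_likelihood_drift(lat.theta[k], xL, net.b, net.N,
                                  lat.alpha, lat.theta0)
        d[lat.banned[k]] = 0.0
        lat.theta[k] = np.maximum(lat.theta[k] + d, -5.0)


def _apply_prior_diffusion(net, span: float, rng: np.random.Generator) -> None:
    for syn in list(net.syn_ff.values()) + [net.syn_lat]:
        dtheta = net.b * span * net.prior.grad_log_density(syn.theta) \
            + np.sqrt(2.0 * net.b * span) * rng.standard_normal(syn.theta.shape)
        theta = np.maximum(syn.theta + dtheta, -5.0)
        theta[syn.banned] = syn.theta[syn.banned]
        syn.theta = theta
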