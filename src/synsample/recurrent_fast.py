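"""Compiled driver for the recurrent bimodal network.

Same model as :func:`synsample.recurrent.simulate_pattern` — per-WTA
softmax rates, double-exponential traces, 5 ms-delayed lateral synapses,
per-postsynaptic-spike STDP sampling updates — with the inner 1 ms loop
compiled by numba.  Input EPSP traces are lazy (amplitude + timestamp),
membrane drives are incremental, and weight caches use second-order
Taylor factors between the exact per-pattern recomputations that
accompany the prior/diffusion update (applied in numpy once per
pattern).  Used by the lesion/compensation experiment, where learning
needs thousands of pattern presentations; the plain numpy path remains
the reference implementation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .recurrent import RecurrentNetwork, _apply_prior_diffusion
from .synthetic import BimodalPattern

__all__ = ["present_pattern_fast"]


@njit(cache=True)
def _present(thetaF, wF, ewF, weffF, bannedF, row_mod_start,
             thetaL, wL, ewL, weffL, bannedL,
             removed, nA_rows, K,
             ratesA, ratesV, n_steps, pad_steps, frame_steps,
             n_A, n_V,
             dec_f, dec_r, adec_f, adec_r, gamma, rho_net, dt,
             b, N, alpha, theta0,
             xf_in, xr_in, last_in, xfL, xrL, ring,
             adf, adr, plastic,
             counts, window_counts, clip_factor):
    """One pattern presentation; mutates all state in place.

    Feedforward matrices are packed into one (n_hidden, n_A + n_V) block
    ``thetaF``: rows of auditory neurons use columns [0, n_A), rows of
    visual neurons use [n_A, n_A + n_V); ``row_mod_start[k]`` gives the
    column offset and ``row_mod_len[k]`` is implied by the modality.
    """
    n_hidden = thetaL.shape[0]
    delay_steps = ring.shape[0]
    clip = clip_factor * b
    w_floor = np.exp(-theta0)

    max_lag = n_steps + 1
    pf = np.empty(max_lag + 1)
    pr = np.empty(max_lag + 1)
    pf[0] = 1.0
    pr[0] = 1.0
    for s in range(1, max_lag + 1):
        pf[s] = pf[s - 1] * dec_f
        pr[s] = pr[s - 1] * dec_r

    n_in = n_A + n_V
    # rebuild drives from surviving traces
    u_f = np.zeros(n_hidden)
    u_r = np.zeros(n_hidden)
    for k in range(n_hidden):
        off = row_mod_start[k]
        ln = n_A if off == 0 else n_V
        acc_f = 0.0
        acc_r = 0.0
        for j in range(ln):
            i = off + j
            acc_f += weffF[k, i] * xf_in[i]
            acc_r += weffF[k, i] * xr_in[i]
        for l in range(n_hidden):
            acc_f += weffL[k, l] * xfL[l]
            acc_r += weffL[k, l] * xrL[l]
        u_f[k] = acc_f
        u_r[k] = acc_r

    ebuf = np.empty(K)
    f = 0
    for s in range(n_steps):
        for k in range(n_hidden):
            u_f[k] *= dec_f
            u_r[k] *= dec_r
            adf[k] *= adec_f
            adr[k] *= adec_r
        for l in range(n_hidden):
            xfL[l] *= dec_f
            xrL[l] *= dec_r

        in_pattern = pad_steps <= s < n_steps - pad_steps
        # input spikes (Bernoulli thinning of the frame rates)
        if in_pattern:
            f = (s - pad_steps) // frame_steps
            if f >= ratesA.shape[0]:
                f = ratesA.shape[0] - 1
        for i in range(n_in):
            if i < n_A:
                rate = ratesA[f, i] if in_pattern else 1.0
            else:
                rate = ratesV[i - n_A] if in_pattern else 1.0
            if np.random.random() < rate * dt:
                lag = s - last_in[i]
                if lag > max_lag:
                    xf_in[i] = 0.0
                    xr_in[i] = 0.0
                else:
                    xf_in[i] *= pf[lag]
                    xr_in[i] *= pr[lag]
                xf_in[i] += 1.0
                xr_in[i] += 1.0
                last_in[i] = s
                if i < n_A:
                    for k in range(nA_rows):  # auditory ensemble rows
                        u_f[k] += weffF[k, i]
                        u_r[k] += weffF[k, i]
                else:
                    for k in range(nA_rows, n_hidden):
                        u_f[k] += weffF[k, i]
                        u_r[k] += weffF[k, i]

        # delayed lateral spikes reach the traces now
        slot = s % delay_steps
        for l in range(n_hidden):
            if ring[slot, l]:
                xfL[l] += 1.0
                xrL[l] += 1.0
                for k in range(n_hidden):
                    u_f[k] += weffL[k, l]
                    u_r[k] += weffL[k, l]
            ring[slot, l] = False

        # per-WTA softmax and spiking
        for g in range(n_hidden // K):
            umax = -1.0e300
            for j in range(K):
                k = g * K + j
                if removed[k]:
                    ebuf[j] = 0.0
                    continue
                uk = u_f[k] - u_r[k] + gamma * (adf[k] - adr[k])
                if uk > umax:
                    umax = uk
            if umax <= -1.0e299:
                continue
            esum = 0.0
            for j in range(K):
                k = g * K + j
                if not removed[k]:
                    uk = u_f[k] - u_r[k] + gamma * (adf[k] - adr[k])
                    ebuf[j] = np.exp(uk - umax)
                    esum += ebuf[j]
            for j in range(K):
                k = g * K + j
                if removed[k]:
                    continue
                rho = rho_net * ebuf[j] / esum
                if np.random.random() < rho * dt:
                    ring[(s + delay_steps) % delay_steps, k] = True
                    adf[k] += 1.0
                    adr[k] += 1.0
                    counts[k] += 1
                    if in_pattern:
                        window_counts[k] += 1
                    if not plastic:
                        continue
                    # feedforward row update
                    off = row_mod_start[k]
                    ln = n_A if off == 0 else n_V
                    acc_f = 0.0
                    acc_r = 0.0
                    for jj in range(ln):
                        i = off + jj
                        lag = s - last_in[i]
                        cf = xf_in[i] * pf[lag] if lag <= max_lag else 0.0
                        cr = xr_in[i] * pr[lag] if lag <= max_lag else 0.0
                        if not bannedF[k, i]:
                            xi = cf - cr
                            d = b * N * wF[k, i] * (xi - alpha * ewF[k, i])
                            if d > clip:
                                d = clip
                            elif d < -clip:
                                d = -clip
                            th = thetaF[k, i] + d
                            if th < -5.0:
                                d = -5.0 - thetaF[k, i]
                                th = -5.0
                            thetaF[k, i] = th
                            wn = wF[k, i] * (1.0 + d + 0.5 * d * d)
                            dw = wn - wF[k, i]
                            ewF[k, i] = ewF[k, i] * (1.0 + dw + 0.5 * dw * dw)
                            wF[k, i] = wn
                            we = wn - w_floor
                            weffF[k, i] = we if we > 0.0 else 0.0
                        acc_f += weffF[k, i] * cf
                        acc_r += weffF[k, i] * cr
                    # lateral row update (eager traces)
                    for l in range(n_hidden):
                        if not bannedL[k, l]:
                            xi = xfL[l] - xrL[l]
                            d = b * N * wL[k, l] * (xi - alpha * ewL[k, l])
                            if d > clip:
                                d = clip
                            elif d < -clip:
                                d = -clip
                            th = thetaL[k, l] + d
                            if th < -5.0:
                                d = -5.0 - thetaL[k, l]
                                th = -5.0
                            thetaL[k, l] = th
                            wn = wL[k, l] * (1.0 + d + 0.5 * d * d)
                            dw = wn - wL[k, l]
                            ewL[k, l] = ewL[k, l] * (1.0 + dw + 0.5 * dw * dw)
                            wL[k, l] = wn
                            we = wn - w_floor
                            weffL[k, l] = we if we > 0.0 else 0.0
                        acc_f += weffL[k, l] * xfL[l]
                        acc_r += weffL[k, l] * xrL[l]
                    u_f[k] = acc_f
                    u_r[k] = acc_r

    # flush input traces to the pattern boundary
    for i in range(n_in):
        lag = n_steps - last_in[i]
        if lag > max_lag:
            xf_in[i] = 0.0
            xr_in[i] = 0.0
        else:
            xf_in[i] *= pf[lag]
            xr_in[i] *= pr[lag]
        last_in[i] = 0


class _FastState:
    """Packed numeric state attached to a RecurrentNetwork."""

    def __init__(self, net: RecurrentNetwork):
        n_A, n_V = net.n_inputs["A"], net.n_inputs["V"]
        nh = net.n_hidden
        self.n_A, self.n_V = n_A, n_V
        self.thetaF = np.full((nh, n_A + n_V), -5.0)
        self.bannedF = np.ones((nh, n_A + n_V), dtype=np.bool_)
        ids_A, ids_V = net.hidden_ids("A"), net.hidden_ids("V")
        self.thetaF[np.ix_(ids_A, np.arange(n_A))] = net.syn_ff["A"].theta
        self.bannedF[np.ix_(ids_A, np.arange(n_A))] = net.syn_ff["A"].banned
        if "V" in net.syn_ff:
            self.thetaF[np.ix_(ids_V, n_A + np.arange(n_V))] = net.syn_ff["V"].theta
            self.bannedF[np.ix_(ids_V, n_A + np.arange(n_V))] = net.syn_ff["V"].banned
        self.row_mod_start = np.where(net.ensemble_of == 0, 0, n_A).astype(np.int64)
        self.refresh_weights(net)
        self.xf_in = np.zeros(n_A + n_V)
        self.xr_in = np.zeros(n_A + n_V)
        self.last_in = np.zeros(n_A + n_V, dtype=np.int64)
        self.xfL = np.zeros(nh)
        self.xrL = np.zeros(nh)
        self.adf = np.zeros(nh)
        self.adr = np.zeros(nh)
        delay_steps = max(int(round(net.syn_lat.delay / 1e-3)), 1)
        self.ring = np.zeros((delay_steps, nh), dtype=np.bool_)
        self.t_accum = 0.0
        self.n_since = 0

    def resync(self, net: RecurrentNetwork) -> None:
        """Reload theta and ban masks from the canonical matrices."""
        ids_A, ids_V = net.hidden_ids("A"), net.hidden_ids("V")
        self.thetaF[np.ix_(ids_A, np.arange(self.n_A))] = net.syn_ff["A"].theta
        self.bannedF[np.ix_(ids_A, np.arange(self.n_A))] = net.syn_ff["A"].banned
        if "V" in net.syn_ff:
            cols = self.n_A + np.arange(self.n_V)
            self.thetaF[np.ix_(ids_V, cols)] = net.syn_ff["V"].theta
            self.bannedF[np.ix_(ids_V, cols)] = net.syn_ff["V"].banned
        self.refresh_weights(net)

    def refresh_weights(self, net: RecurrentNetwork) -> None:
        w_floor = np.exp(-net.syn_lat.theta0)
        self.wF = np.exp(self.thetaF - net.syn_lat.theta0)
        self.ewF = np.exp(self.wF)
        self.weffF = np.maximum(0.0, self.wF - w_floor)
        self.weffF[self.bannedF] = 0.0
        self.wL = net.syn_lat.w
        self.ewL = np.exp(self.wL)
        self.weffL = np.maximum(0.0, self.wL - w_floor)
        self.weffL[net.syn_lat.banned] = 0.0

    def write_back(self, net: RecurrentNetwork) -> None:
        n_A = self.n_A
        ids_A, ids_V = net.hidden_ids("A"), net.hidden_ids("V")
        net.syn_ff["A"].theta = self.thetaF[np.ix_(ids_A, np.arange(n_A))].copy()
        if "V" in net.syn_ff:
            net.syn_ff["V"].theta = self.thetaF[
                np.ix_(ids_V, n_A + np.arange(self.n_V))].copy()


def present_pattern_fast(net: RecurrentNetwork, pattern: BimodalPattern,
                         rng: np.random.Generator, plasticity_on: bool = True,
                         audio_only: bool = False, pad: float = 0.025,
                         dt: float = 1e-3, clip_factor: float = 5.0) -> dict:
    """Drop-in fast equivalent of :func:`synsample.recurrent.simulate_pattern`
    (spike events are not returned, only counts and z_V rates)."""
    from .wta_fast import _seed_rng

    state = getattr(net, "_fast", None)
    if state is None:
        state = _FastState(net)
        net._fast = state
        net._fast_stale = False
        _seed_rng(int(rng.integers(0, 2**31 - 1)))

    nm = net.neuron
    n_steps = int(round((pattern.duration + 2 * pad) / dt))
    pad_steps = int(round(pad / dt))
    frame_steps = max(int(round(pattern.frame_dt / dt)), 1)
    ratesV = np.full(state.n_V, 1.0) if audio_only else pattern.rates_V

    if getattr(net, "_fast_stale", False):
        # lesions changed theta/masks outside the packed state
        state.resync(net)
        net._fast_stale = False

    counts = np.zeros(net.n_hidden, dtype=np.int64)
    window_counts = np.zeros(net.n_hidden, dtype=np.int64)
    nA_rows = int(np.sum(net.ensemble_of == 0))
    _present(state.thetaF, state.wF, state.ewF, state.weffF, state.bannedF,
             state.row_mod_start,
             net.syn_lat.theta, state.wL, state.ewL, state.weffL,
             net.syn_lat.banned, net.removed, nA_rows,
             net.wta_groups.shape[1],
             pattern.rates_A, np.asarray(ratesV, dtype=float),
             n_steps, pad_steps, frame_steps, state.n_A, state.n_V,
             np.exp(-dt / nm.tau_f), np.exp(-dt / nm.tau_r),
             np.exp(-dt / nm.adapt_fall), np.exp(-dt / nm.adapt_rise),
             nm.gamma, nm.rho_net, dt, net.b, net.N,
             net.syn_lat.alpha, net.syn_lat.theta0,
             state.xf_in, state.xr_in, state.last_in, state.xfL, state.xrL,
             state.ring, state.adf, state.adr, plasticity_on,
             counts, window_counts, clip_factor)

    if plasticity_on:
        # prior drift + diffusion amortized over a few patterns (their
        # timescale is hours; Gaussian increments compose exactly)
        state.t_accum += n_steps * dt
        state.n_since += 1
        if state.n_since >= 5:
            state.write_back(net)
            _apply_prior_diffusion(net, state.t_accum, rng)
            state.resync(net)
            state.t_accum = 0.0
            state.n_since = 0

    rates_V = window_counts[net.hidden_ids("V")] / pattern.duration
    return {"counts": counts.astype(float), "rates_V": rates_V,
            "t_max": n_steps * dt}
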