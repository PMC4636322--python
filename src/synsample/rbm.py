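"""Restricted Boltzmann machine with sampling-based plasticity.

The RBM is a bipartite binary network: visible units x (one per pixel) and
hidden units z, symmetric weights w_ij between the layers, logistic-sigmoid
conditional activation.  The likelihood gradient is estimated by
contrastive divergence (CD-k, default k=5): a wake phase clamps the
visible layer to the input and samples the hidden layer once, then k
alternating reconstruction cycles produce the model's own statistics.

The plasticity rule adds a structural weight prior and Gaussian noise to
the CD estimate,

    dw_ij = eta * ( d/dw_ij log p_S(w) + N (z_i x_j - z^_i x^_j) ) + sqrt(2 eta) nu,

which turns maximum-likelihood training into posterior sampling over
weights.  Biases follow the same rule with no prior term.  With few
hidden units the test log-likelihood can be computed exactly by
enumerating hidden configurations, which makes the generalization /
overfitting comparison between priors exact rather than estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .priors import UniformPrior
from .synthetic import BinaryPattern

__all__ = [
    "RBMParams",
    "CDStatistics",
    "init_rbm_params",
    "present_pattern",
    "sample_hidden_given_visible",
    "sample_visible_given_hidden",
    "cd_k_statistics",
    "sampling_update",
    "exact_log_likelihood",
    "train_generalization_experiment",
]

#: hidden-layer size limit for exact enumeration (2^20 states)
MAX_HIDDEN_ENUMERATION = 20


@dataclass
class RBMParams:
    """Weights (hidden x visible) and per-layer biases.

    One matrix serves both directions: connections are bidirectional with
    symmetric weights, so hidden input is ``W @ x`` and visible input is
    ``W.T @ z``.
    """

    weights: np.ndarray
    hidden_biases: np.ndarray
    visible_biases: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[0]

    @property
    def n_visible(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.weights.copy(), self.hidden_biases.copy(),
                         self.visible_biases.copy())


def init_rbm_params(n_visible: int, n_hidden: int, rng: np.random.Generator,
                    sd: float = 0.25, weight_mean: float = 0.0,
                    bias_mean: float = -1.0) -> RBMParams:
    """Random initial parameters: Normal(sd=0.25), means 0 for weights and
    -1 for both bias vectors."""
    return RBMParams(
        weights=rng.normal(weight_mean, sd, size=(n_hidden, n_visible)),
        hidden_biases=rng.normal(bias_mean, sd, size=n_hidden),
        visible_biases=rng.normal(bias_mean, sd, size=n_visible),
    )


def present_pattern(pattern, rng: np.random.Generator) -> np.ndarray:
    """Binarize a pattern for presentation: each visible unit is 1 with
    probability given by the scaled gray level."""
    if isinstance(pattern, BinaryPattern):
        return (rng.uniform(size=pattern.source_intensity.shape)
                < pattern.source_intensity).astype(float)
    return np.asarray(pattern, dtype=float)


def _values(pattern) -> np.ndarray:
    if isinstance(pattern, BinaryPattern):
        return np.asarray(pattern.values, dtype=float)
    return np.asarray(pattern, dtype=float)


def sample_hidden_given_visible(params: RBMParams, visible, rng) -> np.ndarray:
    """Each hidden unit independently Bernoulli(sigma(W x + b_hid))."""
    v = _values(visible)
    if v.shape[-1] != params.n_visible:
        raise ValueError(f"visible length {v.shape[-1]} != {params.n_visible}")
    p = expit(params.weights @ v + params.hidden_biases)
    return (rng.uniform(size=p.shape) < p).astype(float)


def sample_visible_given_hidden(params: RBMParams, hidden, rng) -> np.ndarray:
    h = np.asarray(hidden, dtype=float)
    p = expit(params.weights.T @ h + params.visible_biases)
    return (rng.uniform(size=p.shape) < p).astype(float)


@dataclass
class CDStatistics:
    """Wake and reconstruction statistics of one CD-k pass.

    ``weight_stat`` is z x^T - z^ x^^T; the bias statistics are z - z^ and
    x - x^.  All entries lie in [-1, 1] for binary units.
    """

    wake: np.ndarray            # z x^T
    reconstruction: np.ndarray  # z^ x^^T
    hidden_diff: np.ndarray     # z - z^
    visible_diff: np.ndarray    # x - x^

    @property
    def weight_stat(self) -> np.ndarray:
        return self.wake - self.reconstruction


def cd_k_statistics(params: RBMParams, visible, k: int = 5,
                    rng: np.random.Generator | None = None) -> CDStatistics:
    """CD-k: clamp the visible layer, sample hidden once (wake), then run k
    alternating visible/hidden reconstruction cycles; the states after the
    k-th cycle provide the reconstruction statistics."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    x = _values(visible)
    z = sample_hidden_given_visible(params, x, rng)
    z_hat = z
    for _ in range(k):
        x_hat = sample_visible_given_hidden(params, z_hat, rng)
        z_hat = sample_hidden_given_visible(params, x_hat, rng)
    return CDStatistics(
        wake=np.outer(z, x),
        reconstruction=np.outer(z_hat, x_hat),
        hidden_diff=z - z_hat,
        visible_diff=x - x_hat,
    )


def sampling_update(params: RBMParams, stats: CDStatistics, prior, eta: float,
                    N: int, rng: np.random.Generator,
                    noise_scale: float | None = None) -> RBMParams:
    """One posterior-sampling parameter update from CD statistics.

    Weights get the prior gradient + N * CD statistic + sqrt(2 eta) noise;
    biases get N * CD statistic + noise with no prior term.  Pass
    ``noise_scale=0`` to recover the deterministic (regularized ML) update.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    s = np.sqrt(2.0 * eta) if noise_scale is None else noise_scale * np.sqrt(2.0 * eta)
    w = params.weights + eta * (prior.grad_log_density(params.weights)
                                + N * stats.weight_stat) \
        + s * rng.standard_normal(params.weights.shape)
    bh = params.hidden_biases + eta * N * stats.hidden_diff \
        + s * rng.standard_normal(params.hidden_biases.shape)
    bv = params.visible_biases + eta * N * stats.visible_diff \
        + s * rng.standard_normal(params.visible_biases.shape)
    return RBMParams(w, bh, bv)


def _hidden_states(n_hidden: int) -> np.ndarray:
    # all 2^H binary hidden configurations, rows = states
    return ((np.arange(2**n_hidden)[:, None] >> np.arange(n_hidden)) & 1).astype(float)


def log_partition(params: RBMParams) -> float:
    """log Z by enumerating hidden states; visible units summed analytically
    via the softplus product."""
    if params.n_hidden > MAX_HIDDEN_ENUMERATION:
        raise ValueError(
            f"{params.n_hidden} hidden units exceed the enumeration limit "
            f"({MAX_HIDDEN_ENUMERATION}); use a smaller hidden layer or an "
            "estimated likelihood")
    Z = _hidden_states(params.n_hidden)               # (2^H, H)
    vis_field = Z @ params.weights + params.visible_biases  # (2^H, V)
    log_terms = Z @ params.hidden_biases + np.sum(np.logaddexp(0.0, vis_field), axis=1)
    return float(logsumexp(log_terms))


def exact_log_likelihood(params: RBMParams, patterns) -> float:
    """Mean exact log p(x) over patterns.

    The unnormalized marginal sums hidden units analytically,
    log p~(x) = b_vis . x + sum_i softplus(b_hid_i + w_i . x); the
    partition function enumerates the hidden layer.
    """
    logZ = log_partition(params)
    X = np.asarray([_values(p) for p in patterns], dtype=float)
    hid_field = X @ params.weights.T + params.hidden_biases  # (n, H)
    log_unnorm = X @ params.visible_biases + np.sum(np.logaddexp(0.0, hid_field), axis=1)
    return float(np.mean(log_unnorm) - logZ)


def train_generalization_experiment(train_patterns, test_patterns, prior=None,
                                    eta: float = 1e-4, N: int = 100, k: int = 5,
                                    n_updates: int = 20000, eval_every: int = 500,
                                    seed: int = 0, n_hidden: int = 9,
                                    histogram_bins: int = 80,
                                    histogram_range: tuple = (-4.0, 4.0)) -> dict:
    """Train on a few patterns, track exact train/test log-likelihood curves.

    Each update presents one randomly drawn training pattern (binarized
    from its gray levels), estimates the likelihood gradient with CD-k and
    applies the sampling update.  Returns the curves, the final parameters
    and the final weight histogram (80 bins equally spaced on [-4, 4]).
    With a uniform prior this is noisy maximum-likelihood learning and the
    test curve eventually degrades (overfitting); with a bimodal weight
    prior matched to the two-mode pixel statistics the test performance is
    maintained.
    """
    if prior is None:
        prior = UniformPrior()
    rng = np.random.default_rng(seed)
    n_visible = len(_values(train_patterns[0]))
    params = init_rbm_params(n_visible, n_hidden, rng)

    steps, train_ll, test_ll = [], [], []

    def _evaluate(step):
        steps.append(step)
        train_ll.append(exact_log_likelihood(params, train_patterns))
        test_ll.append(exact_log_likelihood(params, test_patterns))

    _evaluate(0)
    for step in range(1, n_updates + 1):
        pattern = train_patterns[rng.integers(0, len(train_patterns))]
        x = present_pattern(pattern, rng)
        stats = cd_k_statistics(params, x, k=k, rng=rng)
        params = sampling_update(params, stats, prior, eta, N, rng)
        if step % eval_every == 0:
            _evaluate(step)

    hist, edges = np.histogram(params.weights.ravel(), bins=histogram_bins,
                               range=histogram_range)
    return {
        "steps": np.asarray(steps),
        "train_ll": np.asarray(train_ll),
        "test_ll": np.asarray(test_ll),
        "params": params,
        "weight_histogram": hist,
        "histogram_edges": edges,
    }
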