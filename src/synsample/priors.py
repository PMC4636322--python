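"""Prior distributions over synaptic parameters.

Structural priors enter the plasticity rule only through the gradient of
their log-density, so every prior here exposes ``log_density`` and
``grad_log_density``.  All priors are scalar and applied elementwise:
the structural prior over the full parameter vector is assumed to
factorize, which keeps the resulting plasticity rules local.

Three families cover the experiments:

* :class:`GaussianPrior` — the default structural prior on spiking-network
  parameters (mean 0.5, sd 1), which in weight space becomes log-normal.
* :class:`GaussianMixturePrior` — the bimodal weight prior used for
  Bayesian regularization of the Boltzmann machine (modes near 0 and 1).
* :class:`UniformPrior` — improper flat prior with identically zero
  gradient; recovers plain maximum-likelihood updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy import stats

__all__ = [
    "GaussianPrior",
    "GaussianMixturePrior",
    "UniformPrior",
    "prior_from_config",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GaussianPrior:
    """Normal(mu, sigma^2) prior on a scalar parameter."""

    mu: float = 0.5
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        z = (theta - self.mu) / self.sigma
        return -0.5 * z * z - np.log(self.sigma) - 0.5 * _LOG_2PI

    def grad_log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        return (self.mu - theta) / self.sigma**2

    def sample(self, size, rng: np.random.Generator):
        return rng.normal(self.mu, self.sigma, size=size)


@dataclass(frozen=True)
class GaussianMixturePrior:
    """Mixture of normals; default is the bimodal weight prior
    0.5*N(1.0, 0.15^2) + 0.5*N(0.0, 0.15^2)."""

    weights: tuple = (0.5, 0.5)
    means: tuple = (1.0, 0.0)
    sds: tuple = (0.15, 0.15)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if len(self.weights) != len(self.means) or len(self.means) != len(self.sds):
            raise ValueError("weights, means and sds must have equal length")
        if np.any(np.asarray(self.sds, dtype=float) <= 0):
            raise ValueError("all component sds must be > 0")

    def _component_logpdfs(self, theta):
        theta = np.asarray(theta, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        z = (theta[..., None] - mu) / sd
        return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI

    def log_density(self, theta):
        lp = self._component_logpdfs(theta) + np.log(self.weights)
        return logsumexp(lp, axis=-1)

    def responsibilities(self, theta):
        """Posterior probability of each mixture component given theta."""
        lp = self._component_logpdfs(theta) + np.log(self.weights)
        return np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))

    def grad_log_density(self, theta):
        theta = np.asarray(theta, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        resp = self.responsibilities(theta)
        comp_grad = (mu - theta[..., None]) / sd**2
        return np.sum(resp * comp_grad, axis=-1)

    def sample(self, size, rng: np.random.Generator):
        size = (size,) if np.isscalar(size) else tuple(size)
        comp = rng.choice(len(self.weights), size=size, p=np.asarray(self.weights))
        mu = np.asarray(self.means)[comp]
        sd = np.asarray(self.sds)[comp]
        return rng.normal(mu, sd)


@dataclass(frozen=True)
class UniformPrior:
    """Improper flat prior: log-density 0 by convention, gradient exactly 0.

    Using it in a sampling rule recovers the plain (noisy) maximum
    likelihood update.  It cannot be sampled from.
    """

    def log_density(self, theta):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def grad_log_density(self, theta):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def sample(self, size, rng: np.random.Generator):
        raise NotImplementedError("the improper uniform prior cannot be sampled")


_REGISTRY = {
    "gaussian": GaussianPrior,
    "gaussian_mixture": GaussianMixturePrior,
    "uniform": UniformPrior,
}


def prior_from_config(name: str, **params):
    """Build a prior by name, e.g. ``prior_from_config("gaussian", mu=0.5, sigma=1)``.

    Tuple-valued mixture parameters may be given as lists (JSON round-trip).
    """
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown prior {name!r}; one of {sorted(_REGISTRY)}") from None
    params = {k: tuple(v) if isinstance(v, list) else v for k, v in params.items()}
    return cls(**params)
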