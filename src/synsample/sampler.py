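"""Langevin parameter-sampling engine.

The learning goal is not a maximum-likelihood point estimate but the
posterior over network parameters,

    p*(theta | x)  ∝  p_S(theta) * p_N(x | theta),

and the sampler is the Euler–Maruyama discretization of the stochastic
differential equation

    d theta_i = [ b(theta_i) d/dtheta_i log p_S(theta)
                + b(theta_i) d/dtheta_i log p_N(x | theta)
                + T b'(theta_i) ] dt  +  sqrt(2 T b(theta_i)) dW_i,

whose unique stationary distribution is p*(theta)^(1/T) (up to
normalization).  ``T`` is a temperature: T=1 samples the posterior, T->0
approaches MAP convergence.  ``b`` is the learning rate / sampling speed
and may depend on theta; the ``T b'(theta)`` drift correction keeps the
stationary distribution invariant under such modulation.

Online learning replaces the full-data likelihood gradient with
``N * grad log p_N(x^n | theta)`` for the single current input ``x^n``
(:func:`discrete_step`); :func:`batch_step` uses the exact sum over the
dataset.  Reference stationary densities for validating the sampler are
provided by :func:`reference_posterior_density` (direct exponentiation)
and :func:`fokker_planck_stationary_oracle` (zero-flux solution of the
associated Fokker–Planck equation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "ParameterVector",
    "SamplerConfig",
    "GradientModel",
    "ReferenceDensity",
    "discrete_step",
    "batch_step",
    "run_chain",
    "ensemble_stationary_samples",
    "reference_posterior_density",
    "fokker_planck_stationary_oracle",
]


@dataclass
class ParameterVector:
    """Synaptic parameter vector theta with retraction semantics.

    ``theta_i > functional_threshold`` marks a functional connection;
    values are clamped from below at ``clip_low`` after every update.
    """

    values: np.ndarray
    clip_low: float = -5.0
    functional_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("parameter vector contains non-finite entries")

    def functional_mask(self) -> np.ndarray:
        return self.values > self.functional_threshold

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(values, self.clip_low, self.functional_threshold)


@dataclass
class SamplerConfig:
    """Configuration of the discrete-time sampler.

    Parameters
    ----------
    b
        Learning rate.  Either a positive scalar or a function
        ``b(theta) > 0``; in the latter case ``b_prime`` (its analytic
        derivative) must be supplied — no numerical differentiation is
        performed, so the drift correction stays exact.
    temperature_T
        Diffusion scale; stationary density is posterior**(1/T).
    dt
        Integration step in model time units; the small-step contract is
        ``b * dt <= 1e-3`` in the validation suites.
    dataset_size_N
        Multiplier of the single-pattern likelihood gradient in the
        online rule.
    max_step
        Clamp on the per-update parameter change |d theta|; defaults to
        ``5 b`` for scalar b and to no clamp for state-dependent b.
    clip_low
        Lower clamp on theta itself (default -5).
    """

    b: Union[float, Callable[[np.ndarray], np.ndarray]]
    dt: float
    b_prime: Optional[Callable[[np.ndarray], np.ndarray]] = None
    temperature_T: float = 1.0
    dataset_size_N: int = 1
    seed: int = 0
    max_step: Optional[float] = None
    clip_low: float = -5.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature_T < 0:
            raise ValueError("temperature_T must be >= 0")
        if self.dataset_size_N < 1:
            raise ValueError("dataset_size_N must be a positive integer")
        if callable(self.b):
            if self.b_prime is None:
                raise ValueError("state-dependent b requires an analytic b_prime")
        elif self.b <= 0:
            raise ValueError("b must be > 0")
        if self.max_step is None:
            self.max_step = 5.0 * self.b if not callable(self.b) else np.inf

    @property
    def eta(self) -> float:
        """Effective discrete-time learning rate eta = b * dt (scalar b only)."""
        if callable(self.b):
            raise AttributeError("eta is defined only for constant b")
        return self.b * self.dt

    def b_at(self, theta: np.ndarray) -> np.ndarray:
        return self.b(theta) if callable(self.b) else np.broadcast_to(self.b, theta.shape)

    def b_prime_at(self, theta: np.ndarray) -> np.ndarray:
        if callable(self.b):
            return self.b_prime(theta)
        return np.zeros_like(theta)


@dataclass
class GradientModel:
    """Gradient callbacks of the log prior and log likelihood.

    ``prior_grad(theta)`` returns d/dtheta log p_S elementwise.
    ``likelihood_grad(theta, minibatch)`` returns d/dtheta log p_N(x^n|theta)
    (or of the joint with sampled hidden state when one is supplied);
    ``None`` means no likelihood term (prior-only dynamics).
    """

    prior_grad: Callable[[np.ndarray], np.ndarray]
    likelihood_grad: Optional[Callable[[np.ndarray, object], np.ndarray]] = None

    @classmethod
    def from_prior(cls, prior, likelihood_grad=None) -> "GradientModel":
        return cls(prior_grad=prior.grad_log_density, likelihood_grad=likelihood_grad)


def _check_grad(g: np.ndarray, theta: np.ndarray, what: str) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape != theta.shape:
        raise ValueError(
            f"{what} gradient shape {g.shape} does not match theta shape {theta.shape}"
        )
    if not np.all(np.isfinite(g)):
        idx = int(np.flatnonzero(~np.isfinite(g))[0])
        raise FloatingPointError(f"non-finite {what} gradient at parameter index {idx}")
    return g


def _apply_step(theta: np.ndarray, dtheta: np.ndarray, cfg: SamplerConfig) -> np.ndarray:
    dtheta = np.clip(dtheta, -cfg.max_step, cfg.max_step)
    return np.maximum(theta + dtheta, cfg.clip_low)


def discrete_step(theta, grads: GradientModel, minibatch, cfg: SamplerConfig,
                  noise: np.ndarray):
    """One online Euler–Maruyama update on a single input x^n.

    d theta = dt [ b grad_prior + N b grad_lik + T b' ] + sqrt(2 T dt b) * noise,
    followed by the |d theta| <= max_step and theta >= clip_low clamps.
    Deterministic given (theta, minibatch, noise).
    """
    wrapped = isinstance(theta, ParameterVector)
    th = theta.values if wrapped else np.asarray(theta, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != th.shape:
        raise ValueError(f"noise shape {noise.shape} != theta shape {th.shape}")

    b = cfg.b_at(th)
    drift = b * _check_grad(grads.prior_grad(th), th, "prior")
    if grads.likelihood_grad is not None:
        gl = _check_grad(grads.likelihood_grad(th, minibatch), th, "likelihood")
        drift = drift + cfg.dataset_size_N * b * gl
    drift = drift + cfg.temperature_T * cfg.b_prime_at(th)
    dtheta = cfg.dt * drift + np.sqrt(2.0 * cfg.temperature_T * cfg.dt * b) * noise
    out = _apply_step(th, dtheta, cfg)
    return theta.with_values(out) if wrapped else out


def batch_step(theta, grads: GradientModel, full_dataset: Sequence, cfg: SamplerConfig,
               noise: np.ndarray):
    """One exact (batch) update: the likelihood gradient is summed over the
    whole dataset with no N multiplier."""
    if grads.likelihood_grad is not None and len(full_dataset) == 0:
        raise ValueError("batch_step requires a non-empty dataset")
    wrapped = isinstance(theta, ParameterVector)
    th = theta.values if wrapped else np.asarray(theta, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != th.shape:
        raise ValueError(f"noise shape {noise.shape} != theta shape {th.shape}")

    b = cfg.b_at(th)
    drift = b * _check_grad(grads.prior_grad(th), th, "prior")
    if grads.likelihood_grad is not None:
        gsum = np.zeros_like(th)
        for x in full_dataset:
            gsum += _check_grad(grads.likelihood_grad(th, x), th, "likelihood")
        drift = drift + b * gsum
    drift = drift + cfg.temperature_T * cfg.b_prime_at(th)
    dtheta = cfg.dt * drift + np.sqrt(2.0 * cfg.temperature_T * cfg.dt * b) * noise
    out = _apply_step(th, dtheta, cfg)
    return theta.with_values(out) if wrapped else out


def run_chain(theta0, grads: GradientModel, data_stream, cfg: SamplerConfig,
              n_steps: int, thin: int = 1) -> np.ndarray:
    """Run the online sampler for ``n_steps`` and return every ``thin``-th state.

    ``data_stream`` may be None (prior-only), a sequence of inputs cycled in
    order, or a callable ``(step, rng) -> minibatch``.  The noise stream is
    derived from ``cfg.seed`` in a fixed parameter order, so identical seeds
    give bit-identical trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    th = theta0.values.copy() if isinstance(theta0, ParameterVector) else np.array(
        theta0, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    kept = []
    for step in range(n_steps):
        if data_stream is None:
            minibatch = None
        elif callable(data_stream):
            minibatch = data_stream(step, rng)
        else:
            minibatch = data_stream[step % len(data_stream)]
        noise = rng.standard_normal(th.shape)
        th = discrete_step(th, grads, minibatch, cfg, noise)
        if (step + 1) % thin == 0:
            kept.append(th.copy())
    return np.asarray(kept)


def ensemble_stationary_samples(grads: GradientModel, cfg: SamplerConfig,
                                n_samples: int, n_steps: int,
                                init_low: float, init_high: float,
                                data_stream=None) -> np.ndarray:
    """Approximate i.i.d. draws from the 1-D stationary density.

    Runs ``n_samples`` independent scalar chains in parallel (the update
    is elementwise, so the ensemble is just a parameter vector of
    replicas), initialized overdispersed on ``[init_low, init_high]``,
    and returns the final state of each chain.  ``n_steps`` must cover
    several relaxation times of the dynamics.
    """
    rng = np.random.default_rng(cfg.seed)
    th = rng.uniform(init_low, init_high, size=n_samples)
    for step in range(n_steps):
        minibatch = data_stream(step, rng) if callable(data_stream) else data_stream
        noise = rng.standard_normal(th.shape)
        th = discrete_step(th, grads, minibatch, cfg, noise)
    return th


@dataclass
class ReferenceDensity:
    """A normalized 1-D density tabulated on an ordered grid."""

    grid: np.ndarray
    density: np.ndarray
    normalizer_Z: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def cdf(self) -> np.ndarray:
        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        return c / c[-1]

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def var(self) -> float:
        m = self.mean()
        return float(np.trapezoid((self.grid - m) ** 2 * self.density, self.grid))

    def total_variation(self, other: "ReferenceDensity") -> float:
        if not np.allclose(self.grid, other.grid):
            raise ValueError("total variation requires matching grids")
        return 0.5 * float(np.trapezoid(np.abs(self.density - other.density), self.grid))

    def ks_statistic(self, samples: np.ndarray) -> float:
        """Two-sided KS distance between empirical samples and this density."""
        samples = np.sort(np.asarray(samples, dtype=float))
        cdf_at = np.interp(samples, self.grid, self.cdf())
        n = len(samples)
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        return float(max(np.max(ecdf_hi - cdf_at), np.max(cdf_at - ecdf_lo)))


def _normalize_on_grid(grid: np.ndarray, log_unnorm: np.ndarray) -> ReferenceDensity:
    unnorm = np.exp(log_unnorm - np.max(log_unnorm))
    z_rel = float(np.trapezoid(unnorm, grid))
    density = unnorm / z_rel
    # Z on the original (unshifted) scale
    normalizer_Z = z_rel * float(np.exp(np.max(log_unnorm)))
    if max(density[0], density[-1]) > 1e-4 * np.max(density):
        warnings.warn("grid may be too narrow: boundary density exceeds 1e-4 of max",
                      stacklevel=2)
    return ReferenceDensity(grid, density, normalizer_Z)


def reference_posterior_density(log_prior_fn, log_likelihood_fn, T: float,
                                grid: np.ndarray) -> ReferenceDensity:
    """Tempered 1-D posterior ∝ [p_S(theta) p_N(x|theta)]^(1/T) on a grid."""
    grid = np.asarray(grid, dtype=float)
    logq = np.asarray(log_prior_fn(grid), dtype=float).copy()
    if log_likelihood_fn is not None:
        logq += np.asarray(log_likelihood_fn(grid), dtype=float)
    return _normalize_on_grid(grid, logq / T)


def fokker_planck_stationary_oracle(drift_fn, diffusion_fn,
                                    grid: np.ndarray) -> ReferenceDensity:
    """Zero-flux stationary solution of d theta = A dt + sqrt(2 D) dW.

    p(theta) ∝ (1/D(theta)) exp( ∫ A/D dtheta ), computed by cumulative
    trapezoidal integration and normalized on the grid.
    """
    grid = np.asarray(grid, dtype=float)
    D = np.asarray(diffusion_fn(grid), dtype=float)
    if np.any(D <= 0):
        raise ValueError("diffusion must be strictly positive on the grid")
    A = np.asarray(drift_fn(grid), dtype=float)
    potential = cumulative_trapezoid(A / D, grid, initial=0.0)
    return _normalize_on_grid(grid, potential - np.log(D))
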