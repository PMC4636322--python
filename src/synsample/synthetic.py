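"""Synthetic inputs for all experiments.

Four generators:

* :class:`TuningEnvironment` — a population of input neurons with Gaussian
  tuning curves over a low-dimensional "sensory space" (the unit cube);
  a sensory experience is a point in that space, mapped to population
  firing rates.
* :class:`ClusterWorld` — mixture-of-Gaussians distributions over the
  sensory space modelling a standard environment (SE, 3 clusters) and an
  enriched environment (EE, the same clusters plus 4 new ones).
* :func:`digit_pattern_generator` — stroke-like binary images standing in
  for handwritten-digit data: a handful of prototypes per class plus
  per-pixel Bernoulli flip noise, giving the two-mode pixel statistics
  that motivate a bimodal weight prior.
* :func:`bimodal_pattern_generator` — paired "auditory" (temporally
  structured rates, 320–520 ms) and "visual" (static rate image) patterns
  per class, standing in for spoken/written digit pairs.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningEnvironment",
    "ClusterWorld",
    "experience_to_rates",
    "sample_world",
    "rates_to_spikes",
    "BinaryPattern",
    "digit_pattern_generator",
    "bimodal_pattern_generator",
    "BimodalPattern",
]


# ---------------------------------------------------------------------------
# tuning-curve environment

@dataclass
class TuningEnvironment:
    """Population of input neurons with Gaussian tuning over the unit cube.

    Rates are normalized across the population per pattern so the best
    responding neuron fires at ``rate_max`` (80 Hz), on top of a constant
    ``rate_background`` (5 Hz); per-neuron normalization is available via
    ``normalization="per_neuron"`` (then each neuron's tuning peak maps to
    ``rate_max`` regardless of the others).
    """

    n_inputs: int = 1000
    tuning_sd: float = 0.3
    centers: np.ndarray | None = None
    rate_max: float = 80.0
    rate_background: float = 5.0
    pattern_duration: float = 0.2
    dim: int = 3
    normalization: str = "per_pattern"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.centers is None:
            rng = np.random.default_rng(self.seed)
            self.centers = rng.uniform(0.0, 1.0, size=(self.n_inputs, self.dim))
        else:
            self.centers = np.asarray(self.centers, dtype=float)
            self.n_inputs, self.dim = self.centers.shape


def experience_to_rates(env: TuningEnvironment, point: np.ndarray) -> np.ndarray:
    """Firing rates of the input population for one sensory experience."""
    point = np.clip(np.asarray(point, dtype=float), 0.0, 1.0)
    d2 = np.sum((env.centers - point) ** 2, axis=1)
    support = np.exp(-0.5 * d2 / env.tuning_sd**2)
    if env.normalization == "per_pattern":
        support = support / support.max()
    elif env.normalization != "per_neuron":
        raise ValueError(f"unknown normalization {env.normalization!r}")
    return env.rate_max * support + env.rate_background


# ---------------------------------------------------------------------------
# mixture-of-Gaussians worlds

@dataclass
class ClusterWorld:
    """Mixture of Gaussian clusters over the sensory space, equal weights."""

    means: np.ndarray        # (n_components, dim)
    covariances: np.ndarray  # (n_components, dim, dim)

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @staticmethod
    def _make_covariance(dim: int, rng: np.random.Generator) -> np.ndarray:
        # 0.04 I + 0.01 xi with raw normal xi is generically asymmetric and
        # possibly indefinite: symmetrize and floor the eigenvalues.
        xi = rng.normal(0.0, 1.0, size=(dim, dim))
        c = 0.04 * np.eye(dim) + 0.01 * xi
        c = 0.5 * (c + c.T)
        evals, evecs = np.linalg.eigh(c)
        evals = np.maximum(evals, 1e-4)
        return evecs @ np.diag(evals) @ evecs.T

    @classmethod
    def standard(cls, rng: np.random.Generator, n_components: int = 3,
                 dim: int = 3) -> "ClusterWorld":
        means = rng.normal(0.5, 0.2, size=(n_components, dim))
        covs = np.stack([cls._make_covariance(dim, rng) for _ in range(n_components)])
        return cls(means, covs)

    def enriched(self, rng: np.random.Generator, n_extra: int = 4) -> "ClusterWorld":
        """An enriched world strictly extending this one with new clusters."""
        dim = self.means.shape[1]
        extra_means = rng.normal(0.5, 0.2, size=(n_extra, dim))
        extra_covs = np.stack([self._make_covariance(dim, rng) for _ in range(n_extra)])
        return ClusterWorld(np.vstack([self.means, extra_means]),
                            np.concatenate([self.covariances, extra_covs]))


def sample_world(world: ClusterWorld, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n experience points: pick a cluster uniformly, then a Gaussian sample."""
    if n < 1:
        raise ValueError("n must be >= 1")
    comps = rng.integers(0, world.n_components, size=n)
    chols = np.linalg.cholesky(world.covariances)
    z = rng.standard_normal((n, world.means.shape[1]))
    return world.means[comps] + np.einsum("nij,nj->ni", chols[comps], z)


def rates_to_spikes(rates: np.ndarray, duration: float, rng: np.random.Generator,
                    pad: float = 0.0, pad_rate: float = 1.0) -> np.ndarray:
    """Homogeneous Poisson spike trains, one per input neuron.

    Returns an array of (neuron_id, time_s) events sorted by time.  With
    ``pad > 0`` the pattern window is preceded and followed by ``pad``
    seconds of ``pad_rate`` Poisson noise (times then span
    [0, duration + 2 pad) with the pattern starting at ``pad``).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rates = np.asarray(rates, dtype=float)
    events = []

    def _draw(rate_vec, t0, span):
        counts = rng.poisson(np.maximum(rate_vec, 0.0) * span)
        for i in np.nonzero(counts)[0]:
            times = t0 + rng.uniform(0.0, span, size=counts[i])
            events.append(np.column_stack([np.full(counts[i], i), times]))

    if pad > 0:
        _draw(np.full_like(rates, pad_rate), 0.0, pad)
        _draw(rates, pad, duration)
        _draw(np.full_like(rates, pad_rate), pad + duration, pad)
    else:
        _draw(rates, 0.0, duration)
    if not events:
        return np.empty((0, 2))
    ev = np.vstack(events)
    return ev[np.argsort(ev[:, 1], kind="stable")]


# ---------------------------------------------------------------------------
# digit-like binary images

@dataclass
class BinaryPattern:
    """A binarized image pattern and the gray levels it was drawn from."""

    values: np.ndarray            # binary vector in {0, 1}
    source_intensity: np.ndarray  # gray levels in [0, 1]
    label: int = 0


def _stroke_prototype(side: int, col_frac: float, slant: float,
                      thickness: int = 2) -> np.ndarray:
    """A vertical-ish stroke through the image: a schematic handwritten '1'."""
    img = np.zeros((side, side))
    for r in range(1, side - 1):
        c = col_frac * side + slant * (r - side / 2)
        c0 = int(round(c))
        for t in range(thickness):
            cc = c0 + t - thickness // 2
            if 0 <= cc < side:
                img[r, cc] = 1.0
    return img.ravel()


def _cross_prototype(side: int, row_frac: float, col_frac: float,
                     thickness: int = 2) -> np.ndarray:
    """A plus-shaped stroke: a schematic second digit class."""
    img = np.zeros((side, side))
    r0, c0 = int(row_frac * side), int(col_frac * side)
    for t in range(-thickness, thickness + 1):
        img[np.clip(r0 + t, 0, side - 1), 1:side - 1] = 1.0
        img[1:side - 1, np.clip(c0 + t, 0, side - 1)] = 1.0
    return img.ravel()


def class_prototypes(n_classes: int, n_prototypes: int, side: int) -> list[np.ndarray]:
    """Deterministic prototype banks, one list entry (n_prototypes, side^2) per class.

    Stroke styles vary in column position and slant over a central range,
    so different styles overlap in the central stroke region the way
    handwritten digits do, while differing in their exact pixels.
    """
    protos = []
    for cls in range(n_classes):
        bank = []
        denom = max(n_prototypes - 1, 1)
        for p in range(n_prototypes):
            if cls % 2 == 0:
                col = 0.38 + 0.24 * (p / denom)
                slant = -0.18 + 0.36 * (((p * 7) % n_prototypes) / denom)
                bank.append(_stroke_prototype(side, col, slant))
            else:
                row = 0.35 + 0.3 * (p / denom)
                col = 0.35 + 0.3 * (((p * 5) % n_prototypes) / denom)
                bank.append(_cross_prototype(side, row, col))
        protos.append(np.asarray(bank))
    return protos


def digit_pattern_generator(n_train: int = 5, n_test: int = 100,
                            n_classes: int = 1, prototypes_per_class: int = 12,
                            image_side: int = 14, flip_noise: float = 0.05,
                            train_prototypes: int = 2,
                            rng: np.random.Generator | None = None,
                            seed: int = 0):
    """Train/test sets of stroke-like binary patterns.

    The train set draws from a small prototype subset of one class (the
    narrow "training style", taken from the middle of the style range);
    the test set draws from the remaining, disjoint prototypes of the
    same class (the wider variety of styles on either side).  Gray levels
    are prototype pixels damped to [flip_noise, 1-flip_noise];
    binarization samples each pixel Bernoulli(gray), so ``flip_noise = f``
    flips prototype pixels with probability f.
    """
    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(seed)
    protos = class_prototypes(n_classes, prototypes_per_class, image_side)

    def _make(bank_idx, n, cls):
        out = []
        for _ in range(n):
            proto = protos[cls][rng.choice(bank_idx)]
            gray = np.where(proto > 0.5, 1.0 - flip_noise, flip_noise)
            if flip_noise == 0.0:
                values = proto.astype(int)
            else:
                values = (rng.uniform(size=gray.shape) < gray).astype(int)
            out.append(BinaryPattern(values, gray, label=cls))
        return out

    mid = prototypes_per_class // 2
    lo = max(mid - train_prototypes // 2, 0)
    train_idx = np.arange(lo, lo + train_prototypes)
    test_idx = np.setdiff1d(np.arange(prototypes_per_class), train_idx)
    train = _make(train_idx, n_train, 0)
    test = []
    for cls in range(n_classes):
        test += _make(test_idx, n_test // n_classes, cls)
    return train, test


# ---------------------------------------------------------------------------
# bimodal (auditory + visual) class patterns

@dataclass
class BimodalPattern:
    """One paired stimulus: a temporal rate pattern (modality A) and a
    static rate image (modality V), presented simultaneously."""

    label: int
    duration: float                 # s, in [0.32, 0.52]
    rates_A: np.ndarray             # (n_frames, n_A) Hz, 10 ms frames
    rates_V: np.ndarray             # (n_V,) Hz, static
    frame_dt: float = 0.01


def bimodal_pattern_generator(label: int, n_A: int = 770, n_V: int = 784,
                              rng: np.random.Generator | None = None,
                              seed: int = 0,
                              amplitude_jitter: float = 0.1,
                              rate_max_A: float = 80.0,
                              rate_max_V: float = 50.0,
                              noise_rate: float = 1.0) -> BimodalPattern:
    """One synthetic two-class stimulus pair ("spoken" + "written" digit).

    Modality A mimics a cochleagram of 77 frequency channels, each
    represented by 10 afferent neurons (770 total at the default size):
    each class energizes its own band of channels — a sweep (up for
    class 0, down for class 1) through the class's band plus a
    class-specific steady formant-like band — over a duration drawn from
    [320, 520] ms, rates normalized to [0, 80] Hz plus 1 Hz noise.  The
    two classes thus differ both in which channels are active and in
    temporal structure, as spoken words do.  Modality V is a
    class-specific stroke image (28x28 at the default size) scaled to
    [0, 50] Hz plus 1 Hz noise.  Within-class variability comes from
    duration, amplitude jitter and the sweep's start channel.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    duration = rng.uniform(0.32, 0.52)
    frame_dt = 0.01
    n_frames = int(round(duration / frame_dt))
    n_ch = max(min(77, n_A // 10), 4)
    repeat = int(np.ceil(n_A / n_ch))
    channels = np.arange(n_ch)
    # class-specific sweep band: lower half for class 0, upper for class 1
    band_lo = (0.05 if label == 0 else 0.45) * n_ch
    band_hi = (0.55 if label == 0 else 0.95) * n_ch
    start = band_lo + rng.uniform(0.0, 0.1) * n_ch
    span = (band_hi - band_lo) * 0.8
    phase = np.linspace(0.0, 1.0, n_frames)
    center = start + span * (phase if label == 0 else 1.0 - phase)
    width = 0.08 * n_ch
    bump = np.exp(-0.5 * ((channels[None, :] - center[:, None]) / width) ** 2)
    # steady formant band, distinct per class
    formant_c = (0.80 if label == 0 else 0.20) * n_ch
    formant = 0.6 * np.exp(-0.5 * ((channels - formant_c) / (0.05 * n_ch)) ** 2)
    amp = 1.0 + amplitude_jitter * rng.standard_normal(n_frames)
    rates_ch = rate_max_A * (bump + formant[None, :]) \
        * np.clip(amp, 0.5, 1.5)[:, None] + noise_rate
    rates_ch = np.minimum(rates_ch, rate_max_A + noise_rate)
    rates_A = np.repeat(rates_ch, repeat, axis=1)[:, :n_A]

    side = int(round(np.sqrt(n_V)))
    protos = class_prototypes(2, 4, side)
    proto = protos[label][rng.integers(0, 4)]
    gain = 1.0 + amplitude_jitter * rng.standard_normal()
    rates_V = rate_max_V * proto[:n_V] * np.clip(gain, 0.5, 1.5) + noise_rate
    return BimodalPattern(label, duration, rates_A, rates_V, frame_dt)
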