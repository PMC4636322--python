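"""Spine-turnover statistics: formation/elimination events, survival curves, fits.

A synapse is functional when its parameter theta exceeds 0.  Presence is
evaluated on a fixed sampling grid (30-minute intervals by default, matching
the cadence of chronic imaging studies); a formation event is a crossing from
theta <= 0 at one sample to theta > 0 at the next, an elimination event the
converse.  Survival curves track the fraction of a newly-formed cohort still
functional as a function of the lag since formation.  The stationary regime
of the sampling dynamics yields power-law-like survival; transient regimes
are well described by a two-term exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEFAULT_GRID_S",
    "SurvivalTable",
    "FitResult",
    "detect_events",
    "formation_rate",
    "survival_curve",
    "fit_survival",
]

#: default presence-evaluation interval: 30 minutes, in seconds
DEFAULT_GRID_S = 1800.0


@dataclass
class SurvivalTable:
    """Per-lag survival of a cohort of newly formed synapses.

    ``surviving_fraction[0]`` is 1 by definition (survival at formation);
    the fraction is non-increasing in lag because a synapse leaves the
    surviving set permanently at its first elimination after formation.
    """

    lags: np.ndarray                 # seconds since formation
    surviving_fraction: np.ndarray   # in [0, 1], non-increasing
    n_tracked: int                   # cohort size

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags,
                             "surviving_fraction": self.surviving_fraction})


@dataclass
class FitResult:
    model: str               # "power_law" | "two_term_exponential"
    params: np.ndarray
    r_squared: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "power_law":
            a, gamma = self.params
            return a * t ** (-gamma)
        a, tau1, c, tau2 = self.params
        return a * np.exp(-t / tau1) + c * np.exp(-t / tau2)


def detect_events(theta_trajectory: np.ndarray, sample_times: np.ndarray,
                  threshold: float = 0.0) -> pd.DataFrame:
    """Threshold-crossing events of theta sampled at ``sample_times``.

    Parameters
    ----------
    theta_trajectory
        Array (n_times, n_synapses) of parameter samples; a 1-D array is
        treated as a single synapse.
    sample_times
        Strictly increasing times (s) of the rows.

    Returns
    -------
    DataFrame with columns ``synapse``, ``time_s`` (the sample at which the
    new state is first seen) and ``kind`` ("formation" or "elimination").
    """
    theta = np.asarray(theta_trajectory, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None]
    times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if len(times) != theta.shape[0]:
        raise ValueError("sample_times length must match trajectory rows")

    present = theta > threshold
    formed = ~present[:-1] & present[1:]
    eliminated = present[:-1] & ~present[1:]
    rows = []
    for kind, mask in (("formation", formed), ("elimination", eliminated)):
        t_idx, s_idx = np.nonzero(mask)
        for ti, si in zip(t_idx, s_idx):
            rows.append((int(si), float(times[ti + 1]), kind))
    df = pd.DataFrame(rows, columns=["synapse", "time_s", "kind"])
    return df.sort_values(["time_s", "synapse"], kind="stable").reset_index(drop=True)


def formation_rate(events: pd.DataFrame, window: float = DEFAULT_GRID_S,
                   t_start: float = 0.0, t_end: float | None = None,
                   n_potential: int | None = None) -> pd.DataFrame:
    """Formation counts per consecutive time window.

    Returns a DataFrame with the window end time, the raw count, and (if
    ``n_potential`` is given) the count normalized by the number of
    potential synapses.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    formations = events[events["kind"] == "formation"]
    if t_end is None:
        t_end = float(formations["time_s"].max()) if len(formations) else t_start + window
    edges = np.arange(t_start, t_end + window * 0.5, window)
    if len(edges) < 2:
        edges = np.array([t_start, t_start + window])
    # events are stamped at the grid sample where the new state is first
    # seen, so a window (a, b] owns events at exactly b: shift below the
    # edge so histogram's half-open bins count them in the right window
    counts, _ = np.histogram(formations["time_s"] - 1e-9 * window, bins=edges)
    out = pd.DataFrame({"window_end_s": edges[1:], "count": counts})
    if n_potential:
        out["rate_per_synapse"] = out["count"] / n_potential
    return out


def survival_curve(formation_events: pd.DataFrame, theta_trajectory: np.ndarray,
                   sample_times: np.ndarray, horizon: float,
                   threshold: float = 0.0) -> SurvivalTable:
    """Survival of the cohort formed at the given events.

    For each lag on the sampling grid, the surviving fraction counts
    synapses that stayed functional at *every* grid point from formation
    through that lag (first elimination removes a synapse permanently —
    reappearance after elimination is a new synapse).  Lags extending past
    the recorded trajectory are dropped for that synapse (right censoring).
    """
    theta = np.asarray(theta_trajectory, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None]
    times = np.asarray(sample_times, dtype=float)
    step = float(times[1] - times[0]) if len(times) > 1 else DEFAULT_GRID_S
    n_lags = int(round(horizon / step)) + 1
    lags = np.arange(n_lags) * step

    formations = formation_events[formation_events["kind"] == "formation"]
    if len(formations) == 0:
        warnings.warn("no formation events; returning empty survival table",
                      stacklevel=2)
        return SurvivalTable(lags, np.full(n_lags, np.nan), 0)

    present = theta > threshold
    at_risk = np.zeros(n_lags, dtype=int)
    alive = np.zeros(n_lags, dtype=int)
    for _, ev in formations.iterrows():
        syn = int(ev["synapse"])
        i0 = int(np.argmin(np.abs(times - ev["time_s"])))
        still = True
        for k in range(n_lags):
            if i0 + k >= len(times):
                break
            at_risk[k] += 1
            still = still and bool(present[i0 + k, syn])
            if still:
                alive[k] += 1
    frac = np.where(at_risk > 0, alive / np.maximum(at_risk, 1), np.nan)
    return SurvivalTable(lags, frac, int(len(formations)))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_res <= 1e-9 * max(float(np.sum(y**2)), 1e-30):
        return 1.0  # zero-residual (degenerate perfect) fit
    if ss_tot <= 1e-30:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_survival(table: SurvivalTable, model: str = "power_law") -> FitResult:
    """Least-squares fit of a survival curve.

    ``power_law``: s(t) = a * t^(-gamma), fitted excluding lag 0 (survival
    at formation is 1 by definition and log 0 is undefined); the initial
    estimate comes from a log-log linear regression, refined by nonlinear
    least squares.  ``two_term_exponential``: s(t) = a e^(-t/tau1) + c e^(-t/tau2).
    """
    mask = np.isfinite(table.surviving_fraction)
    lags, frac = table.lags[mask], table.surviving_fraction[mask]
    if len(lags) < 5:
        raise ValueError("need at least 5 lag points to fit")

    if model == "power_law":
        pos = (lags > 0) & (frac > 0)
        if pos.sum() < 3:
            raise ValueError("too few positive points for a power-law fit")
        t, s = lags[pos], frac[pos]
        slope, intercept, *_ = stats.linregress(np.log(t), np.log(s))
        p0 = [float(np.exp(intercept)), float(-slope)]
        try:
            params, _ = optimize.curve_fit(
                lambda tt, a, g: a * tt ** (-g), t, s, p0=p0, maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(f"power-law fit did not converge: {err}") from err
        return FitResult("power_law", np.asarray(params), _r_squared(
            s, params[0] * t ** (-params[1])))

    if model == "two_term_exponential":
        t, s = lags, frac
        span = max(float(t[-1]), 1.0)
        p0 = [0.6 * s[0], span / 10.0, 0.4 * s[0], span]
        try:
            params, _ = optimize.curve_fit(
                lambda tt, a, t1, c, t2: a * np.exp(-tt / t1) + c * np.exp(-tt / t2),
                t, s, p0=p0,
                bounds=([0, 1e-9, 0, 1e-9], [np.inf] * 4), maxfev=40000)
        except RuntimeError as err:
            raise RuntimeError(f"two-term exponential fit did not converge: {err}") from err
        a, t1, c, t2 = params
        return FitResult("two_term_exponential", np.asarray(params), _r_squared(
            s, a * np.exp(-t / t1) + c * np.exp(-t / t2)))

    raise ValueError(f"unknown model {model!r}")
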