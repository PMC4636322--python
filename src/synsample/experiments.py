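"""Reproducible experiment drivers.

Each driver is a pure function of (config, seed) returning a plain-dict
report; the CLI wraps these and writes the reports to disk.  Default
scales are chosen so each driver completes in minutes on one CPU; the
reference scale for the environment-adaptation experiment is the full
3 h SE / 1 h EE / 5 h {SE|EE} schedule with 1000 inputs, which the
compiled spiking driver handles directly.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

from . import structural, synthetic, wta
from .priors import GaussianMixturePrior, GaussianPrior, UniformPrior
from .recurrent import build_recurrent_network, lesion
from .rbm import train_generalization_experiment
from .sampler import (GradientModel, SamplerConfig, ensemble_stationary_samples,
                      fokker_planck_stationary_oracle, reference_posterior_density)
from .synthetic import ClusterWorld, TuningEnvironment, digit_pattern_generator

__all__ = [
    "run_sampler_validation",
    "run_rbm_experiment",
    "run_adaptation_experiment",
    "run_lesion_experiment",
    "detect_histogram_modes",
]


# ---------------------------------------------------------------------------
# sampler validation suite

def run_sampler_validation(seed: int = 0, n_samples: int = 50_000,
                           fast: bool = False) -> dict:
    """Numerical verification that the sampler's stationary law is the
    tempered posterior: KS against the analytic Gaussian, the variance
    ∝ T temperature law, the b(theta) drift-correction invariance, and
    the Fokker–Planck/posterior-density oracle cross-check."""
    if fast:
        n_samples = min(n_samples, 10_000)
    prior = GaussianPrior(0.5, 1.0)
    grads = GradientModel.from_prior(prior)
    report: dict = {"seed": seed}

    # 1. Gaussian-prior chain vs Normal(0.5, 1)
    cfg = SamplerConfig(b=1.0, dt=1e-3, seed=seed)
    samples = ensemble_stationary_samples(grads, cfg, n_samples, n_steps=8000,
                                          init_low=-2.0, init_high=3.0)
    ks = float(stats.kstest(samples, stats.norm(0.5, 1.0).cdf).statistic)
    report["gaussian_chain"] = {
        "mean": float(samples.mean()), "var": float(samples.var()),
        "ks": ks, "n": int(n_samples),
        "mean_ok": abs(samples.mean() - 0.5) < 3.0 / np.sqrt(n_samples),
        "var_ok": abs(samples.var() - 1.0) < 3.0 * np.sqrt(2.0 / n_samples),
        "ks_ok": ks < 0.03,
    }

    # 2. temperature law: empirical variance scales linearly with T
    variances = {}
    for i, T in enumerate((0.5, 1.0, 2.0)):
        cfg_t = SamplerConfig(b=1.0, dt=1e-3, temperature_T=T, seed=seed + 100 + i)
        s = ensemble_stationary_samples(grads, cfg_t, n_samples // 2, n_steps=8000,
                                        init_low=-2.0, init_high=3.0)
        variances[T] = float(s.var())
    ratios = {T: variances[T] / (T * 1.0) for T in variances}
    report["temperature_law"] = {
        "variances": {str(k): v for k, v in variances.items()},
        "ratio_ok": all(abs(r - 1.0) < 0.10 for r in ratios.values()),
    }

    # 3. state-dependent sampling speed: the T b'(theta) correction keeps
    #    the stationary density invariant; omitting it tilts the density
    b0 = 1.0
    b_fn = lambda th: b0 * (1.0 + 0.5 * np.tanh(th))
    b_prime = lambda th: 0.5 * b0 / np.cosh(th) ** 2
    cfg_mod = SamplerConfig(b=b_fn, b_prime=b_prime, dt=1e-3, seed=seed + 7,
                            max_step=np.inf)
    s_corr = ensemble_stationary_samples(grads, cfg_mod, n_samples // 2,
                                         n_steps=10_000, init_low=-2.0, init_high=3.0)
    cfg_nc = SamplerConfig(b=b_fn, b_prime=lambda th: np.zeros_like(th), dt=1e-3,
                           seed=seed + 7, max_step=np.inf)
    s_nc = ensemble_stationary_samples(grads, cfg_nc, n_samples // 2,
                                       n_steps=10_000, init_low=-2.0, init_high=3.0)
    ks_corr = float(stats.kstest(s_corr, stats.norm(0.5, 1.0).cdf).statistic)
    ks_nc = float(stats.kstest(s_nc, stats.norm(0.5, 1.0).cdf).statistic)
    report["speed_invariance"] = {"ks_corrected": ks_corr, "ks_uncorrected": ks_nc,
                                  "ok": ks_corr < 0.03 and ks_nc > ks_corr}

    # 4. Fokker-Planck oracle vs direct tempered-posterior density
    mix = GaussianMixturePrior()
    lik_sd = 0.5
    log_lik = lambda th: stats.norm(th, lik_sd).logpdf(0.5)
    grid = np.linspace(-1.5, 2.5, 2001)
    ref = reference_posterior_density(mix.log_density, log_lik, T=1.0, grid=grid)
    b = 1.0
    drift = lambda th: b * (mix.grad_log_density(th) + (0.5 - th) / lik_sd**2)
    fp = fokker_planck_stationary_oracle(drift, lambda th: b * np.ones_like(th), grid)
    report["fp_oracle"] = {"tv": ref.total_variation(fp),
                           "ok": ref.total_variation(fp) < 1e-6}
    report["ok"] = all(report[k]["ok"] if "ok" in report[k]
                       else all(v for kk, v in report[k].items() if kk.endswith("_ok"))
                       for k in ("gaussian_chain", "temperature_law",
                                 "speed_invariance", "fp_oracle"))
    return report


# ---------------------------------------------------------------------------
# RBM generalization experiment

def detect_histogram_modes(hist: np.ndarray, edges: np.ndarray,
                           smooth_bins: float = 1.5) -> np.ndarray:
    """Locations (bin centers) of histogram modes, strongest first."""
    from scipy.ndimage import gaussian_filter1d
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = gaussian_filter1d(hist.astype(float), smooth_bins)
    peaks, props = signal.find_peaks(smoothed, height=0.05 * smoothed.max())
    order = np.argsort(props["peak_heights"])[::-1]
    return centers[peaks[order]]


def _decline(steps: np.ndarray, ll: np.ndarray) -> dict:
    """Overfitting statistics of one test-likelihood curve.

    ``below_peak``: the late mean (last quarter) sits significantly
    (2 within-curve sds) below the curve's early peak — the overfitting
    signature expected without a prior.  ``late_decline``: the last
    quarter is significantly below the third quarter, i.e. performance is
    still degrading late in training; its absence is the stability
    expected with a matched prior (an early transient settling onto a
    plateau does not count as late decline)."""
    n = len(ll)
    q = max(n // 4, 2)
    late = ll[-q:]
    mid = ll[-2 * q:-q]
    peak = float(np.max(ll))
    late_mean = float(np.mean(late))
    late_sd = float(np.std(late))
    return {"peak": peak, "late_mean": late_mean, "late_sd": late_sd,
            "mid_mean": float(np.mean(mid)),
            "decline": peak - late_mean,
            "below_peak": late_mean < peak - 2.0 * late_sd,
            "late_decline": late_mean < float(np.mean(mid)) - 2.0 * late_sd}


def run_rbm_experiment(seed: int = 0, n_seeds: int = 5, image_side: int = 14,
                       n_hidden: int = 9, n_train: int = 5, n_test: int = 100,
                       n_updates: int = 20_000, eval_every: int = 500,
                       eta: float = 1e-4, N: int = 100) -> dict:
    """Generalization with and without a weight prior, matched seeds.

    For each seed the same train/test patterns and parameter
    initialization are used for the uniform-prior (plain noisy ML) and
    bimodal-prior conditions.  Reports the learning curves, overfitting
    verdicts, and the final weight histogram of the bimodal condition
    (80 bins on [-4, 4])."""
    runs = {"uniform": [], "bimodal": []}
    for s in range(n_seeds):
        train, test = digit_pattern_generator(
            n_train=n_train, n_test=n_test, image_side=image_side, seed=seed + s)
        for name, prior in (("uniform", UniformPrior()),
                            ("bimodal", GaussianMixturePrior())):
            res = train_generalization_experiment(
                train, test, prior=prior, eta=eta, N=N, n_updates=n_updates,
                eval_every=eval_every, seed=seed + s, n_hidden=n_hidden)
            res["verdict"] = _decline(res["steps"], res["test_ll"])
            runs[name].append(res)

    uniform_overfits = sum(r["verdict"]["below_peak"] for r in runs["uniform"])
    bimodal_stable = sum(not r["verdict"]["late_decline"] for r in runs["bimodal"])
    hist = np.sum([r["weight_histogram"] for r in runs["bimodal"]], axis=0)
    modes = detect_histogram_modes(hist, runs["bimodal"][0]["histogram_edges"])
    return {
        "runs": runs,
        "seed": seed,
        "config": {"image_side": image_side, "n_hidden": n_hidden,
                   "n_train": n_train, "n_updates": n_updates, "eta": eta, "N": N},
        "n_seeds": n_seeds,
        "uniform_overfit_count": int(uniform_overfits),
        "bimodal_stable_count": int(bimodal_stable),
        "weight_histogram": hist,
        "histogram_edges": runs["bimodal"][0]["histogram_edges"],
        "histogram_modes": modes,
    }


# ---------------------------------------------------------------------------
# environment-adaptation experiment (formation rates + survival)

#: reference schedule: presentations per phase (200 ms each)
SE_PRESENTATIONS = 54_000   # 3 h
EE_PRESENTATIONS = 18_000   # 1 h
PHASE3_PRESENTATIONS = 90_000  # 5 h


def _stable_fraction(presence: np.ndarray, cohort: np.ndarray) -> float:
    """Fraction of cohort synapses continuously present from their formation
    snapshot through the final snapshot.

    ``presence``: (n_snapshots, n_synapses) booleans; ``cohort``: rows of
    (snapshot_index_of_formation, synapse_index)."""
    if len(cohort) == 0:
        return float("nan")
    ok = 0
    for i0, syn in cohort:
        ok += bool(np.all(presence[i0:, syn]))
    return ok / len(cohort)


def run_adaptation_experiment(seed: int = 0, n_seeds: int = 5, scale: float = 1.0,
                              n_inputs: int = 1000, block_size: int = 5,
                              snapshot_interval: float | None = None,
                              driver: str = "spiking") -> dict:
    """SE(3h) -> EE(1h) -> {SE | EE}(5h) with the mean-field WTA driver.

    Tracks synapse presence (theta > 0) on a 30-minute grid, detects
    formation events, and reports (a) the formation-rate time series and
    (b) the survival of the EE-formed cohort under both phase-3 worlds.
    ``scale`` multiplies all phase durations (1.0 = reference schedule); the
    presence-evaluation grid scales with it so each phase keeps the same
    number of windows.  ``driver`` selects the full time-stepped spiking
    dynamics ("spiking", compiled, the default) or the mean-field
    pattern-level approximation ("meanfield", pure numpy, faster but
    known to overestimate the EE-SE surviving fraction).
    """
    if snapshot_interval is None:
        snapshot_interval = 1800.0 * scale
    n_se = max(int(SE_PRESENTATIONS * scale), 1)
    n_ee = max(int(EE_PRESENTATIONS * scale), 1)
    n_p3 = max(int(PHASE3_PRESENTATIONS * scale), 1)

    per_seed = []
    for s in range(n_seeds):
        env = TuningEnvironment(n_inputs=n_inputs, seed=seed + 1000 + s)
        world_rng = np.random.default_rng(seed + 2000 + s)
        se = ClusterWorld.standard(world_rng, n_components=3)
        ee = se.enriched(world_rng, n_extra=4)

        if driver == "spiking":
            from .wta_fast import SpikingWTAFast
            model = SpikingWTAFast(n_inputs=n_inputs, seed=seed + 3000 + s)
        elif driver == "meanfield":
            model = wta.MeanFieldWTA(n_inputs=n_inputs, seed=seed + 3000 + s)
        else:
            raise ValueError(f"unknown driver {driver!r}")
        snaps = model.run_phase(env, se, n_se, block_size, snapshot_interval)
        snaps = model.run_phase(env, ee, n_ee, block_size, snapshot_interval,
                                snapshots=snaps)
        t_se_end = n_se * env.pattern_duration
        t_ee_end = (n_se + n_ee) * env.pattern_duration

        branches = {}
        for cond, world in (("EE-SE", se), ("EE-EE", ee)):
            m = model.copy()
            snaps_b = m.run_phase(env, world, n_p3, block_size, snapshot_interval,
                                  snapshots=[x for x in snaps])
            times = np.array([t for t, _ in snaps_b])
            presence = np.array([p.ravel() for _, p in snaps_b])
            events = structural.detect_events(presence.astype(float), times,
                                              threshold=0.5)
            rate = structural.formation_rate(events, window=snapshot_interval,
                                             t_start=times[0], t_end=times[-1])
            in_ee = (events["kind"] == "formation") & \
                (events["time_s"] > t_se_end + 1e-9) & \
                (events["time_s"] <= t_ee_end + 1e-9)
            cohort_events = events[in_ee]
            snap_idx = {t: i for i, t in enumerate(times)}
            cohort = [(snap_idx[t], syn) for syn, t in
                      zip(cohort_events["synapse"], cohort_events["time_s"])]
            table = structural.survival_curve(
                cohort_events, presence.astype(float), times,
                horizon=n_p3 * env.pattern_duration, threshold=0.5)
            branches[cond] = {
                "formation_rate": rate,
                "n_formed_in_ee": int(len(cohort_events)),
                "stable_fraction": _stable_fraction(presence, cohort),
                "survival": table,
            }
        # formation-rate ordering evaluated on the shared phases 1-2
        r = branches["EE-SE"]["formation_rate"]
        last_se = r[np.isclose(r["window_end_s"], t_se_end)]["count"]
        first_ee = r[np.isclose(r["window_end_s"], t_se_end + snapshot_interval)]["count"]
        per_seed.append({
            "branches": branches,
            "formation_last_se": int(last_se.iloc[0]) if len(last_se) else 0,
            "formation_first_ee": int(first_ee.iloc[0]) if len(first_ee) else 0,
        })

    def _collect(cond, key):
        return np.array([p["branches"][cond][key] for p in per_seed], dtype=float)

    report = {
        "scale": scale, "seed": seed, "n_seeds": n_seeds,
        "config": {"n_inputs": n_inputs, "block_size": block_size,
                   "snapshot_interval": snapshot_interval, "driver": driver,
                   "n_presentations": [n_se, n_ee, n_p3]},
        "per_seed": per_seed,
        "stable_fraction": {c: {"mean": float(np.nanmean(_collect(c, "stable_fraction"))),
                                "sd": float(np.nanstd(_collect(c, "stable_fraction"))),
                                "values": _collect(c, "stable_fraction").tolist()}
                            for c in ("EE-SE", "EE-EE")},
        "formation_rate_rises": int(sum(p["formation_first_ee"] > p["formation_last_se"]
                                        for p in per_seed)),
    }
    # mean survival curves and two-term exponential fits
    for cond in ("EE-SE", "EE-EE"):
        tables = [p["branches"][cond]["survival"] for p in per_seed]
        lags = tables[0].lags
        frac = np.nanmean([t.surviving_fraction for t in tables], axis=0)
        mean_table = structural.SurvivalTable(lags, frac,
                                              sum(t.n_tracked for t in tables))
        entry = {"mean_survival": mean_table}
        try:
            entry["fit"] = structural.fit_survival(mean_table, "two_term_exponential")
        except (RuntimeError, ValueError) as err:
            entry["fit_error"] = str(err)
        report[cond] = entry
    return report


# ---------------------------------------------------------------------------
# lesion / compensation experiment

def _probe_block(net, rng, n_trials: int) -> dict:
    """Audio-only probe trials with plasticity frozen (b = 0).

    Class order is shuffled: the slow adaptation current carries state
    between trials, and a deterministic alternation would leak the
    previous trial's class into the features."""
    from .recurrent_fast import present_pattern_fast
    order = rng.permutation(np.repeat([0, 1], n_trials // 2 + 1))[:n_trials]
    feats, labels = [], []
    for label in order:
        label = int(label)
        pat = synthetic.bimodal_pattern_generator(
            label, n_A=net.n_inputs["A"], n_V=net.n_inputs["V"], rng=rng)
        out = present_pattern_fast(net, pat, rng, plasticity_on=False,
                                   audio_only=True)
        feats.append(out["rates_V"])
        labels.append(label)
    return {"features": np.asarray(feats), "labels": np.asarray(labels)}


def _readout_accuracy(features: np.ndarray, labels: np.ndarray,
                      seed: int = 0) -> float:
    """Cross-validated linear-readout accuracy on z_V rate vectors."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    clf = LogisticRegression(max_iter=2000, C=1.0)
    cv = StratifiedKFold(n_splits=4, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(clf, features, labels, cv=cv)))


def _transfer_accuracy(train_probe: dict, test_probe: dict) -> float:
    """Accuracy of a readout fitted on an earlier probe block and applied
    unchanged to a later one — the 'immediate' performance right after a
    perturbation, before any downstream re-learning."""
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit(train_probe["features"], train_probe["labels"])
    return float(clf.score(test_probe["features"], test_probe["labels"]))


def _class2_selective_neurons(net, probe: dict) -> np.ndarray:
    """z_V neurons preferring class 2 (label 1): higher mean probe rate for
    class-1 trials in the majority of trial pairings."""
    f, y = probe["features"], probe["labels"]
    prefers = f[y == 1].mean(axis=0) > f[y == 0].mean(axis=0)
    return net.hidden_ids("V")[prefers]


def _train_block(net, rng, n_patterns: int) -> None:
    from .recurrent_fast import present_pattern_fast
    for i in range(n_patterns):
        pat = synthetic.bimodal_pattern_generator(
            i % 2, n_A=net.n_inputs["A"], n_V=net.n_inputs["V"], rng=rng)
        present_pattern_fast(net, pat, rng, plasticity_on=True, audio_only=False)


def run_lesion_experiment(seed: int = 0, n_train: int = 9000, n_recover1: int = 4000,
                          n_recover2: int = 4000, n_probe: int = 64,
                          n_inputs_A: int = 770, n_inputs_V: int = 784) -> dict:
    """Train the recurrent bimodal network, lesion it twice, track recovery.

    Checkpoints measure linear-readout accuracy of the auditory stimulus
    class from z_V rates during audio-only probes (plasticity frozen).
    Two accuracies are tracked: the within-block cross-validated accuracy
    (the information currently available in z_V) and, after each lesion,
    the transfer accuracy of the readout fitted before the lesion (the
    immediate performance before downstream re-learning).  Lesion 1
    removes the z_V neurons tuned to class 2; lesion 2 removes all
    currently functional lateral synapses and bans their regrowth.
    """
    rng = np.random.default_rng(seed)
    net = build_recurrent_network(n_inputs_A=n_inputs_A, n_inputs_V=n_inputs_V,
                                  seed=seed)
    timeline = []
    probes = {}

    def checkpoint(name, transfer_from=None):
        probe = _probe_block(net, rng, n_probe)
        probes[name] = probe
        entry = {"checkpoint": name,
                 "accuracy": _readout_accuracy(probe["features"],
                                               probe["labels"], seed),
                 "functional_lateral": net.functional_lateral_count(),
                 "banned_functional": int(np.sum(
                     (net.syn_lat.theta > 0) & net.syn_lat.banned))}
        if transfer_from is not None:
            entry["transfer_accuracy"] = _transfer_accuracy(probes[transfer_from],
                                                            probe)
        timeline.append(entry)
        return probe

    _train_block(net, rng, n_train)
    probe = checkpoint("pre_lesion1")

    selective = _class2_selective_neurons(net, probe)
    lesion(net, "remove_neurons", selective)
    checkpoint("post_lesion1", transfer_from="pre_lesion1")

    _train_block(net, rng, n_recover1)
    checkpoint("post_recovery1")

    lesion(net, "remove_lateral_synapses", net.syn_lat.functional())
    checkpoint("post_lesion2", transfer_from="post_recovery1")

    _train_block(net, rng, n_recover2)
    checkpoint("post_recovery2")

    acc = {t["checkpoint"]: t["accuracy"] for t in timeline}
    imm = {t["checkpoint"]: t.get("transfer_accuracy") for t in timeline}
    return {
        "timeline": timeline,
        "seed": seed,
        "config": {"n_train": n_train, "n_recover1": n_recover1,
                   "n_recover2": n_recover2, "n_probe": n_probe,
                   "n_inputs_A": n_inputs_A, "n_inputs_V": n_inputs_V},
        "n_removed_neurons": int(len(selective)),
        "orderings": {
            "lesion1_drop": imm["post_lesion1"] < acc["pre_lesion1"],
            "lesion1_recovery": acc["post_recovery1"] > imm["post_lesion1"],
            "lesion2_drop": imm["post_lesion2"] < acc["post_recovery1"],
            "lesion2_recovery": acc["post_recovery2"] > imm["post_lesion2"],
            "final_above_chance": acc["post_recovery2"] > 0.5,
            "banned_never_functional": all(t["banned_functional"] == 0
                                           for t in timeline),
        },
    }
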