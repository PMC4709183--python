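"""End-to-end validation scenarios with known ground truth.

Each runner simulates data under stated conditions, executes the regular
pipeline, and returns the measured quantities. The brute-force PLV here is
an *independent oracle*: a direct complex-sum transcription of the PLV
definition in plain Python loops, sharing no code with the vectorized
pipeline it checks.

Problem sizes are deliberate: structural identities run at the reference
acquisition scale (19 channels, 500 Hz), while the stochastic decoding
scenarios run at 8 channels and 100 Hz — the phase statistics under test
depend on trial counts and band, not on montage density or sampling rate,
and the smaller geometry keeps repeated simulation affordable.
"""

from __future__ import annotations

import cmath

import numpy as np
from scipy import stats as sp_stats

from . import connectivity as conn
from . import decode
from .containers import EpochSet
from .paradigm import build_schedule, default_matrix, expected_counts
from .preprocess import extract_epochs, preprocess_recording
from .synth import SimulationConfig, make_fixture, preset_config, simulate_session

__all__ = [
    "bruteforce_plv",
    "run_counting_identities",
    "run_plv_oracle",
    "run_null_calibration",
    "run_edge_recovery",
    "run_character_prediction",
    "run_auc_curve",
    "run_condition_contrast",
]


# --------------------------------------------------------------------------
# independent oracle


def bruteforce_plv(phases: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    """PLV by direct complex summation (pure Python, no vectorization).

    ``phases`` is (trials, channels, samples); returns the upper-triangle
    pair list and a (pairs, samples) PLV array.
    """
    n_trials, n_ch, n_samp = phases.shape
    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    out = np.empty((len(pairs), n_samp))
    for p, (i, j) in enumerate(pairs):
        for t in range(n_samp):
            acc = 0j
            for n in range(n_trials):
                acc += cmath.exp(1j * (phases[n, i, t] - phases[n, j, t]))
            out[p, t] = abs(acc) / n_trials
    return pairs, out


# --------------------------------------------------------------------------
# shared pipeline steps


def _preprocess(rec, zscore: bool = True) -> EpochSet:
    return preprocess_recording(rec, zscore=zscore)


def _subseed(seed: int, k: int) -> int:
    return int((seed * 100003 + 7919 * k + 1) % (2**31 - 1))


# --------------------------------------------------------------------------
# scenario runners


def run_counting_identities(seed: int = 0) -> dict:
    """Structural counts of the reference paradigm, measured by enumeration.

    Builds the 5x6, 14-character, 15-repetition session, simulates it at 19
    channels / 500 Hz, epochs it, and counts what actually comes out.
    """
    rec, _ = make_fixture("reference", rng_seed=seed)
    epochs = extract_epochs(rec)
    n_target = int(epochs.is_target.sum())
    n_nontarget = int((~epochs.is_target).sum())
    phases = conn.instantaneous_phase(epochs.select(np.arange(4)))
    plv = conn.plv_timecourse(phases)
    plan = build_schedule(default_matrix(), list(range(14)), 15, rng_seed=seed)
    return {
        "n_target": n_target,
        "n_nontarget": n_nontarget,
        "n_pairs": len(plv.pairs),
        "samples_per_epoch": epochs.n_samples,
        "expected_counts": expected_counts(plan),
        "n_epochs": epochs.n_trials,
    }


def run_plv_oracle(seed: int = 0) -> dict:
    """Pipeline PLV vs the brute-force oracle, plus known closed forms.

    On random phases (4 channels x 6 trials x 20 samples) the vectorized
    PLV must match the direct complex sum to machine precision. Identical
    phase tensors on two channels give PLV = 1. For independent uniform
    phases at Tr = 100 the time-mean PLV approaches the Rayleigh resultant
    mean sqrt(pi)/(2 sqrt(Tr)) ~ 0.0886, and E[PLV^2] = 1/Tr.
    """
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, (6, 4, 20))
    tensor = conn.PhaseTensor(phases, np.arange(20.0), 1000.0)
    pipeline = conn.plv_timecourse(tensor).plv
    _, oracle = bruteforce_plv(phases)
    max_diff = float(np.abs(pipeline - oracle).max())

    ident = phases.copy()
    ident[:, 1, :] = ident[:, 0, :]
    plv_ident = conn.plv_timecourse(conn.PhaseTensor(ident, np.arange(20.0), 1000.0))
    plv_identical = float(plv_ident.plv[0].min())  # pair (0, 1)

    tr = 100
    n_t = 400
    uni = rng.uniform(-np.pi, np.pi, (tr, 2, n_t))
    plv_u = conn.plv_timecourse(conn.PhaseTensor(uni, np.arange(float(n_t)), 1000.0))
    rayleigh_mean = float(plv_u.plv.mean())
    mean_plv_sq = float((plv_u.plv**2).mean())
    return {
        "bruteforce_max_abs_diff": max_diff,
        "plv_identical_phases": plv_identical,
        "rayleigh_time_mean": rayleigh_mean,
        "rayleigh_expected": float(np.sqrt(np.pi) / (2 * np.sqrt(tr))),
        "mean_plv_squared": mean_plv_sq,
        "expected_plv_squared": 1.0 / tr,
        "n_time_points": n_t,
    }


def _single_character_config(seed: int, coupling, jitter: float,
                             erp_amplitude: float = 8.0,
                             erp_channels=(8, 9, 17, 18),
                             noise_model: str = "one_over_f") -> SimulationConfig:
    """One character, 30 repetitions, 19 channels at 500 Hz."""
    plan = build_schedule(default_matrix(), [0], n_repetitions=30, rng_seed=seed)
    return SimulationConfig(
        plan=plan,
        n_channels=19,
        fs=500.0,
        erp_amplitude=erp_amplitude,
        erp_channels=tuple(erp_channels) if erp_amplitude else (),
        coupling_pairs=tuple(coupling),
        phase_jitter_sd=jitter,
        noise_model=noise_model,
        rng_seed=seed,
    )


def run_null_calibration(seed: int = 0, n_runs: int = 12,
                         n_surrogates: int = 200, alpha: float = 0.01) -> dict:
    """Surrogate-test false-positive rate under the no-coupling null.

    Each run simulates a 19-channel session with no injected coupling and no
    evoked response, takes the 30 trials of one stimulus, and tests all 171
    pairs at ``alpha``; across runs that is >= 2000 pair tests. Returns the
    retained-edge fraction and the binomial 95% interval around ``alpha``.

    The background here is white (then band-passed): the rank test's null
    assumes trials are independent, and the 1/f default's multi-second
    autocorrelation at the band's low edge makes trials cut 250 ms apart
    weakly dependent, which would confound a calibration check.
    """
    n_sig = 0
    n_tests = 0
    for r in range(n_runs):
        s = _subseed(seed, r)
        cfg = _single_character_config(s, coupling=(), jitter=0.0,
                                       erp_amplitude=0.0, noise_model="white")
        rec, _ = simulate_session(cfg)
        epochs = _preprocess(rec)
        group = epochs.select(epochs.stimulus_ids == 0)
        graph = conn.window_average(
            conn.plv_timecourse(conn.instantaneous_phase(group))
        )
        surr = conn.make_surrogates(
            group, n_surrogates=n_surrogates, rng_seed=s, alpha=alpha
        )
        sig = conn.significant_edges(graph, surr)
        n_sig += sig.edge_count
        n_tests += len(surr.pairs)
    lo, hi = sp_stats.binom.interval(0.95, n_tests, alpha)
    return {
        "n_significant": n_sig,
        "n_tests": n_tests,
        "fraction": n_sig / n_tests,
        "alpha": alpha,
        "ci_low": int(lo),
        "ci_high": int(hi),
        "within_ci": bool(lo <= n_sig <= hi),
    }


def run_edge_recovery(seed: int = 0, n_seeds: int = 20,
                      jitter: float = 0.3, n_surrogates: int = 200) -> dict:
    """Sensitivity and false-positive rate of significant-edge detection.

    Simulates 19-channel sessions with the preset parieto-occipital coupling
    set (7 true edges) at the per-character trial count (Tr = 30 target
    trials) and phase jitter ``jitter``, and scores the detected edge set of
    the target-row stimulus against ground truth; medians over seeds.
    """
    coupling = preset_config("reference").coupling_pairs
    true_edges = frozenset(tuple(sorted(p)) for p in coupling)
    sens, fprs = [], []
    for r in range(n_seeds):
        s = _subseed(seed, 1000 + r)
        cfg = _single_character_config(s, coupling=coupling, jitter=jitter)
        rec, truth = simulate_session(cfg)
        epochs = _preprocess(rec)
        group = epochs.select(epochs.stimulus_ids == 0)  # target row of char 0
        graph = conn.window_average(
            conn.plv_timecourse(conn.instantaneous_phase(group))
        )
        surr = conn.make_surrogates(group, n_surrogates=n_surrogates, rng_seed=s)
        detected = conn.significant_edges(graph, surr).edge_set()
        n_pairs = len(surr.pairs)
        sens.append(len(detected & true_edges) / len(true_edges))
        fprs.append(len(detected - true_edges) / (n_pairs - len(true_edges)))
    return {
        "median_sensitivity": float(np.median(sens)),
        "median_fpr": float(np.median(fprs)),
        "n_seeds": n_seeds,
        "n_true_edges": len(true_edges),
        "tr": 30,
    }


def _decoding_config(seed: int, jitter: float, coupling) -> SimulationConfig:
    """14 characters x 15 repetitions at the reduced decoding geometry."""
    plan = build_schedule(default_matrix(), list(range(14)), 15, rng_seed=seed)
    return SimulationConfig(
        plan=plan,
        n_channels=8,
        fs=100.0,
        erp_channels=(6, 7),
        coupling_pairs=tuple(coupling),
        phase_jitter_sd=jitter,
        rng_seed=seed,
    )


_STRONG_COUPLING = ((4, 5), (4, 6), (5, 6), (2, 3))
_MODERATE_COUPLING = ((2, 3), (2, 4), (3, 4), (5, 6), (5, 7), (6, 7))


def run_character_prediction(seed: int = 0, n_seeds: int = 10,
                             n_surrogates: int = 200) -> dict:
    """Spelling accuracy of max-edge row x column intersection.

    Strong-coupling sessions (phase jitter 0.25 rad), 14 characters x 15
    repetitions; for every character each of its 11 stimulus sets gets a
    significance-thresholded graph and the predicted character is the
    intersection of the max-edge row and column. Median accuracy over seeds.
    """
    accs = []
    for r in range(n_seeds):
        s = _subseed(seed, 2000 + r)
        cfg = _decoding_config(s, jitter=0.25, coupling=_STRONG_COUPLING)
        rec, _ = simulate_session(cfg)
        epochs = _preprocess(rec)
        graphs = decode.stimulus_graphs(epochs, n_surrogates=n_surrogates, rng_seed=s)
        n_correct = 0
        for ci, char in enumerate(cfg.plan.characters):
            per_stim = {
                stim: graphs[(ci, stim)] for stim in range(cfg.plan.matrix.n_stimuli)
            }
            pred = decode.predict_character(per_stim, cfg.plan.matrix)
            n_correct += pred.character_index == char
        accs.append(100.0 * n_correct / len(cfg.plan.characters))
    return {
        "median_accuracy_pct": float(np.median(accs)),
        "accuracies": accs,
        "n_seeds": n_seeds,
        "n_characters": 14,
    }


def run_auc_curve(seed: int = 0,
                  trial_counts=(2, 3, 4, 6, 8, 11, 15),
                  n_repeats: int = 20,
                  n_sessions: int = 2) -> dict:
    """AUC of the mean-PLV feature as a function of trials averaged.

    Moderate-coupling sessions (phase jitter 0.9 rad, six true edges) are
    decoded at increasing per-set trial counts; for each count the mean-PLV
    feature is recomputed on random subsets and scored by character-grouped
    SVM splits. The median AUC per count pools the split repeats of all
    sessions (so the Monte-Carlo error of the median is small relative to
    the AUC rise being measured); the Spearman rank correlation between
    trial count and median AUC quantifies the improvement with averaging.
    """
    import pandas as pd

    frames = []
    for sess in range(n_sessions):
        cfg = _decoding_config(_subseed(seed, 3000 + sess), jitter=0.9,
                               coupling=_MODERATE_COUPLING)
        rec, _ = simulate_session(cfg)
        epochs = _preprocess(rec)
        report = decode.auc_vs_trials(
            epochs,
            {"mean_plv": ("mean_plv",)},
            trial_counts,
            n_repeats=n_repeats,
            rng_seed=_subseed(seed, 3100 + sess),
        )
        frames.append(report.results)
    pooled = pd.concat(frames, ignore_index=True)
    medians = pooled.groupby("n_trials")["auc"].median()
    rho = sp_stats.spearmanr(medians.index.to_numpy(), medians.to_numpy()).statistic
    return {
        "spearman_rho": float(rho),
        "trial_counts": [int(k) for k in medians.index],
        "median_auc": [float(v) for v in medians],
        "n_repeats": n_repeats,
        "n_sessions": n_sessions,
    }


def run_condition_contrast(seed: int = 0, n_surrogates: int = 200) -> dict:
    """Wilcoxon rank-sum contrast of per-character edge counts.

    On the strong-coupling reference-scale fixture, each character yields a
    target edge count (its 30 target trials) and a non-target edge count
    (a 30-trial subset of its 135 non-target trials, matched in size because
    the PLV null level depends on the trial count). The two 14-sample groups
    are contrasted with the two-sided rank-sum test.
    """
    rec, _ = make_fixture("reference", rng_seed=seed)
    epochs = _preprocess(rec)
    rng = np.random.default_rng(_subseed(seed, 4000))
    target_counts, nontarget_counts = [], []
    for ci in range(14):
        char_mask = epochs.character_indices == ci
        for condition, store in (("target", target_counts),
                                 ("nontarget", nontarget_counts)):
            mask = char_mask & (
                epochs.is_target if condition == "target" else ~epochs.is_target
            )
            idx = np.nonzero(mask)[0]
            if condition == "nontarget":
                idx = rng.choice(idx, size=30, replace=False)
            group = epochs.select(np.sort(idx))
            graph = conn.window_average(
                conn.plv_timecourse(conn.instantaneous_phase(group))
            )
            surr = conn.make_surrogates(
                group, n_surrogates=n_surrogates, rng_seed=_subseed(seed, 4100 + ci)
            )
            store.append(conn.significant_edges(graph, surr).edge_count)
    statistic, p = conn.condition_contrast(target_counts, nontarget_counts)
    return {
        "statistic": statistic,
        "p_value": p,
        "target_edge_counts": target_counts,
        "nontarget_edge_counts": nontarget_counts,
        "mean_target_edges": float(np.mean(target_counts)),
        "mean_nontarget_edges": float(np.mean(nontarget_counts)),
    }
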