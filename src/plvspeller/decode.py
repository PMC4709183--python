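"""Target/non-target classification and character prediction.

Observations are *stimulus trial sets*: for each attended character, the
trials of one row/column stimulus are pooled, features are computed on the
pooled set (ERP peak and area on the trial-averaged waveform; mean PLV and
significant-edge count on the across-trial connectivity graph), and a
linear SVM separates target from non-target sets. Characters are predicted
without a classifier, by intersecting the row and the column whose graphs
carry the most significant edges.

Cross-validation splits by character — all row/column observations of one
attended character stay on the same side of the split — so no trial set of
a test character leaks into training. The 2:(n_stimuli-2) class imbalance
is handled with class-weighted SVM loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import connectivity as conn
from .containers import EpochSet
from .erp import P300Window, ERPWaveform, area_feature, peak_picking
from .errors import DomainError
from .paradigm import SpellerMatrix

__all__ = [
    "FeatureTable",
    "EvaluationReport",
    "PredictionResult",
    "stimulus_graphs",
    "build_features",
    "classify_cv",
    "predict_character",
    "auc_vs_trials",
    "compare_algorithms",
    "BASELINE_REGISTRY",
]

FEATURE_NAMES = ("peak", "area", "mean_plv", "edge_count")

#: Named slots for third-party comparator algorithms. The bundled baselines
#: are the feature sets defined here; xDAWN and SWLDA are pluggable hooks
#: that callers may register with their own implementations.
BASELINE_REGISTRY: dict[str, object] = {"xdawn": None, "swlda": None}


@dataclass
class FeatureTable:
    """One row per stimulus trial set, with its features and label."""

    frame: pd.DataFrame
    feature_names: tuple[str, ...]

    def __post_init__(self):
        if self.frame["is_target"].isna().any():
            raise DomainError("missing labels in feature table")
        X = self.frame[list(self.feature_names)].to_numpy(float)
        if not np.isfinite(X).all():
            raise DomainError("non-finite feature values")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["is_target"].to_numpy(bool)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class EvaluationReport:
    """Per-algorithm accuracy/AUC, optionally as a function of trial count."""

    results: pd.DataFrame  # columns: algorithm, n_trials, repeat, accuracy_pct, auc
    n_repeats: int
    comparisons: dict = field(default_factory=dict)

    def median_auc(self, algorithm: str) -> pd.Series:
        sub = self.results[self.results["algorithm"] == algorithm]
        return sub.groupby("n_trials")["auc"].median()

    def summary(self) -> pd.DataFrame:
        return (
            self.results.groupby(["algorithm", "n_trials"])
            .agg(accuracy_pct=("accuracy_pct", "mean"), auc_median=("auc", "median"))
            .reset_index()
        )

    def to_json(self, path) -> None:
        import json

        payload = {
            "n_repeats": self.n_repeats,
            "results": self.results.to_dict(orient="records"),
            "comparisons": {str(k): v for k, v in self.comparisons.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class PredictionResult:
    row_id: int
    col_id: int
    character_index: int
    tie_broken: bool


def _set_erp(group: EpochSet) -> ERPWaveform:
    values = group.data.mean(axis=0).mean(axis=0)
    cond = "target" if bool(group.is_target[0]) else "nontarget"
    return ERPWaveform(values, group.time_ms, group.n_trials, cond)


def stimulus_graphs(
    epochs: EpochSet,
    n_surrogates: int = conn.DEFAULT_N_SURROGATES,
    window_ms: tuple[float, float] = conn.DEFAULT_WINDOW_MS,
    alpha: float = conn.DEFAULT_ALPHA,
    rng_seed: int = 0,
    significance: bool = True,
) -> dict[tuple[int, int], conn.ConnectivityGraph]:
    """Connectivity graph per (character, stimulus) trial set.

    Pools the trials of each stimulus set and runs phase -> PLV ->
    window-average. With ``significance`` (the default) each graph is also
    thresholded against its own surrogate null, which the edge-count
    feature requires; weight-only features (mean PLV) can skip it.
    """
    graphs: dict[tuple[int, int], conn.ConnectivityGraph] = {}
    keys = sorted(
        set(zip(epochs.character_indices.tolist(), epochs.stimulus_ids.tolist()))
    )
    for n, (char, stim) in enumerate(keys):
        mask = (epochs.character_indices == char) & (epochs.stimulus_ids == stim)
        group = epochs.select(mask)
        phases = conn.instantaneous_phase(group)
        graph = conn.window_average(
            conn.plv_timecourse(phases), window_ms, epochs.channel_labels
        )
        if significance:
            surr = conn.make_surrogates(
                group,
                n_surrogates=n_surrogates,
                window_ms=window_ms,
                rng_seed=rng_seed + 7919 * n,
                alpha=alpha,
            )
            graph = conn.significant_edges(graph, surr)
        graphs[(char, stim)] = graph
    return graphs


def build_features(
    epochs: EpochSet,
    graphs: dict[tuple[int, int], conn.ConnectivityGraph] | None,
    feature_set,
    p300_window: P300Window = P300Window(),
) -> FeatureTable:
    """One feature row per (character, stimulus) trial set.

    ``feature_set`` is any non-empty subset of ``{"peak", "area",
    "mean_plv", "edge_count"}``; columns appear in that canonical order.
    Connectivity features require ``graphs`` keyed by (character_index,
    stimulus_id) consistently with the epochs.
    """
    features = tuple(f for f in FEATURE_NAMES if f in set(feature_set))
    if not features:
        raise DomainError(f"empty or unknown feature set {feature_set!r}")
    needs_graphs = bool({"mean_plv", "edge_count"} & set(features))
    keys = sorted(
        set(zip(epochs.character_indices.tolist(), epochs.stimulus_ids.tolist()))
    )
    if needs_graphs:
        if graphs is None or set(graphs) != set(keys):
            raise DomainError("graphs do not match the epoch (character, stimulus) keys")

    rows = []
    for char, stim in keys:
        mask = (epochs.character_indices == char) & (epochs.stimulus_ids == stim)
        group = epochs.select(mask)
        row = {
            "character_index": char,
            "stimulus_id": stim,
            "is_target": bool(group.is_target[0]),
            "n_trials_averaged": group.n_trials,
        }
        if "peak" in features or "area" in features:
            erp = _set_erp(group)
            if "peak" in features:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row["peak"] = peak_picking(erp, p300_window)
            if "area" in features:
                row["area"] = area_feature(erp, p300_window)
        if needs_graphs:
            g = graphs[(char, stim)]
            if "mean_plv" in features:
                row["mean_plv"] = conn.mean_plv_feature(g)
            if "edge_count" in features:
                row["edge_count"] = g.edge_count
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows), features)


def _fit_score(table: FeatureTable, train_chars, test_chars):
    from sklearn.metrics import roc_auc_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    df = table.frame
    tr = df["character_index"].isin(train_chars).to_numpy()
    te = df["character_index"].isin(test_chars).to_numpy()
    clf = make_pipeline(
        StandardScaler(),
        LinearSVC(class_weight="balanced", C=1.0, max_iter=10000),
    )
    clf.fit(table.X[tr], table.y[tr])
    scores = clf.decision_function(table.X[te])
    pred = scores > 0
    accuracy = 100.0 * float((pred == table.y[te]).mean())
    auc = float(roc_auc_score(table.y[te], scores))
    return accuracy, auc


def classify_cv(
    table: FeatureTable,
    n_repeats: int = 10,
    train_fraction: float = 0.8,
    rng_seed: int = 0,
    algorithm: str = "linear_svm",
) -> EvaluationReport:
    """Repeated character-grouped train/test evaluation of a linear SVM.

    Characters are randomly split ``train_fraction`` / rest per repeat; the
    classifier is fit on the training characters' trial sets and scored on
    the held-out characters (accuracy of the signed decision, AUC of the
    decision function). Deterministic under a fixed seed.
    """
    if algorithm != "linear_svm":
        raise DomainError(f"unknown classifier {algorithm!r}")
    if n_repeats < 1:
        raise DomainError("n_repeats must be >= 1")
    y = table.y
    if y.all() or not y.any():
        raise DomainError("feature table contains a single class")
    chars = np.unique(table.frame["character_index"])
    n_train = int(round(train_fraction * len(chars)))
    if not 0 < n_train < len(chars):
        raise DomainError("train fraction leaves an empty train or test set")

    rng = np.random.default_rng(rng_seed)
    rows = []
    n_trials = int(table.frame["n_trials_averaged"].max())
    for rep in range(n_repeats):
        perm = rng.permutation(chars)
        accuracy, auc = _fit_score(table, perm[:n_train], perm[n_train:])
        rows.append(
            {
                "algorithm": "+".join(table.feature_names),
                "n_trials": n_trials,
                "repeat": rep,
                "accuracy_pct": accuracy,
                "auc": auc,
            }
        )
    return EvaluationReport(pd.DataFrame(rows), n_repeats)


def predict_character(
    graphs: dict[int, conn.ConnectivityGraph], matrix: SpellerMatrix
) -> PredictionResult:
    """Predict the attended character from per-stimulus connectivity graphs.

    The predicted row (column) is the row (column) stimulus whose graph has
    the most significant edges; the character sits at their intersection.
    Ties are resolved by higher mean PLV, then by lowest stimulus id, and
    the result records that a tie-break happened.
    """
    if set(graphs) != set(range(matrix.n_stimuli)):
        raise DomainError(
            f"need one graph per stimulus id 0..{matrix.n_stimuli - 1}"
        )

    def best(ids):
        counts = {s: graphs[s].edge_count for s in ids}
        top = max(counts.values())
        cands = [s for s in ids if counts[s] == top]
        tie = len(cands) > 1
        if tie:
            mplv = {s: conn.mean_plv_feature(graphs[s]) for s in cands}
            top_plv = max(mplv.values())
            cands = [s for s in cands if mplv[s] == top_plv]
        return min(cands), tie

    row_id, tie_r = best(range(matrix.n_rows))
    col_id, tie_c = best(range(matrix.n_rows, matrix.n_stimuli))
    return PredictionResult(
        row_id=row_id,
        col_id=col_id,
        character_index=matrix.character_at(row_id, col_id),
        tie_broken=tie_r or tie_c,
    )


def auc_vs_trials(
    epochs: EpochSet,
    feature_sets: dict[str, tuple[str, ...]],
    trial_counts,
    n_repeats: int = 10,
    train_fraction: float = 0.8,
    rng_seed: int = 0,
    n_surrogates: int = conn.DEFAULT_N_SURROGATES,
    window_ms: tuple[float, float] = conn.DEFAULT_WINDOW_MS,
) -> EvaluationReport:
    """AUC of each feature set as a function of trials averaged per set.

    For each trial count ``k`` and repeat, a random ``k``-subset of every
    stimulus set's trials is drawn, features are recomputed on the subset,
    and one character-grouped train/test split is scored. Trial counts below
    2 are rejected whenever a PLV-based feature is requested — across-trial
    phase consistency is undefined on a single trial.
    """
    trial_counts = [int(k) for k in trial_counts]
    keys = sorted(
        set(zip(epochs.character_indices.tolist(), epochs.stimulus_ids.tolist()))
    )
    min_avail = min(
        int(((epochs.character_indices == c) & (epochs.stimulus_ids == s)).sum())
        for c, s in keys
    )
    if max(trial_counts) > min_avail:
        raise DomainError(
            f"max trial count {max(trial_counts)} exceeds the {min_avail} "
            "available trials per stimulus set"
        )
    chars = np.unique(epochs.character_indices)
    n_train = int(round(train_fraction * len(chars)))
    if not 0 < n_train < len(chars):
        raise DomainError("train fraction leaves an empty train or test set")

    rng = np.random.default_rng(rng_seed)
    rows = []
    for k in trial_counts:
        plv_requested = any(
            {"mean_plv", "edge_count"} & set(fs) for fs in feature_sets.values()
        )
        if k < 2 and plv_requested:
            raise DomainError("PLV features need at least 2 trials per set")
        for rep in range(n_repeats):
            # one shared trial subsample and character split per repeat
            sub_idx = []
            for char, stim in keys:
                idx = np.nonzero(
                    (epochs.character_indices == char)
                    & (epochs.stimulus_ids == stim)
                )[0]
                sub_idx.extend(rng.choice(idx, size=k, replace=False))
            sub = epochs.select(np.asarray(sorted(sub_idx)))
            needs_graphs = any(
                {"mean_plv", "edge_count"} & set(fs) for fs in feature_sets.values()
            )
            needs_edges = any(
                "edge_count" in fs for fs in feature_sets.values()
            )
            graphs = (
                stimulus_graphs(
                    sub,
                    n_surrogates=n_surrogates,
                    window_ms=window_ms,
                    rng_seed=int(rng.integers(2**31)),
                    significance=needs_edges,
                )
                if needs_graphs
                else None
            )
            perm = rng.permutation(chars)
            for name, fs in feature_sets.items():
                table = build_features(sub, graphs, fs)
                accuracy, auc = _fit_score(table, perm[:n_train], perm[n_train:])
                rows.append(
                    {
                        "algorithm": name,
                        "n_trials": k,
                        "repeat": rep,
                        "accuracy_pct": accuracy,
                        "auc": auc,
                    }
                )
    return EvaluationReport(pd.DataFrame(rows), n_repeats)


def compare_algorithms(
    report: EvaluationReport, pair: tuple[str, str]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between two algorithms' AUC samples."""
    a, b = pair
    xa = report.results.loc[report.results["algorithm"] == a, "auc"].to_numpy()
    xb = report.results.loc[report.results["algorithm"] == b, "auc"].to_numpy()
    if len(xa) < 5 or len(xb) < 5:
        raise DomainError("need at least 5 AUC observations per algorithm")
    res = sp_stats.ranksums(xa, xb)
    return float(res.statistic), float(res.pvalue)
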