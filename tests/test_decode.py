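"""Feature tables, SVM evaluation, character prediction, comparisons."""

import numpy as np
import pandas as pd
import pytest

from plvspeller import connectivity as conn
from plvspeller import decode
from plvspeller.errors import DomainError
from plvspeller.paradigm import SpellerMatrix, default_matrix

from conftest import make_epochs


def speller_epochs(n_chars=14, n_stim=11, n_trials_per_set=2, n_ch=2,
                   n_samp=500, seed=0, separation=0.0):
    """Epochs with full (character, stimulus) metadata; target sets get an
    extra ``separation`` offset in the P300 window."""
    rng = np.random.default_rng(seed)
    rows, chars, stims, targets = [], [], [], []
    for c in range(n_chars):
        tgt = {c % 5, 5 + c % 6}  # row id, column id on the 5x6 grid
        for s in range(n_stim):
            for _ in range(n_trials_per_set):
                trial = rng.standard_normal((n_ch, n_samp))
                if s in tgt:
                    trial[:, 250:300] += separation
                rows.append(trial)
                chars.append(c)
                stims.append(s)
                targets.append(s in tgt)
    return make_epochs(np.stack(rows), is_target=targets, stimulus_ids=stims,
                       character_indices=chars)


def graph_with_edges(n_edges, n_ch=6, mean_plv=0.5):
    weights = np.full((n_ch, n_ch), mean_plv)
    np.fill_diagonal(weights, 0.0)
    adjacency = np.zeros((n_ch, n_ch), bool)
    ii, jj = np.triu_indices(n_ch, k=1)
    for k in range(n_edges):
        adjacency[ii[k], jj[k]] = adjacency[jj[k], ii[k]] = True
    return conn.ConnectivityGraph(weights, (200.0, 500.0), 10, adjacency=adjacency)


class TestBuildFeatures:
    def test_one_row_per_stimulus_set(self):
        epochs = speller_epochs()
        table = decode.build_features(epochs, None, ("peak",))
        assert len(table.frame) == 154
        assert table.feature_names == ("peak",)
        assert int(table.y.sum()) == 28  # 2 target sets per character

    def test_canonical_column_order(self):
        epochs = speller_epochs(n_chars=2)
        graphs = {
            key: graph_with_edges(2, n_ch=4)
            for key in {(c, s) for c, s in zip(epochs.character_indices,
                                               epochs.stimulus_ids)}
        }
        table = decode.build_features(epochs, graphs,
                                      ("mean_plv", "area", "peak"))
        assert table.feature_names == ("peak", "area", "mean_plv")

    def test_empty_feature_set_rejected(self):
        with pytest.raises(DomainError):
            decode.build_features(speller_epochs(n_chars=2), None, ())
        with pytest.raises(DomainError):
            decode.build_features(speller_epochs(n_chars=2), None, ("amplitude",))

    def test_connectivity_features_need_matching_graphs(self):
        epochs = speller_epochs(n_chars=2)
        with pytest.raises(DomainError):
            decode.build_features(epochs, {}, ("edge_count",))


class TestClassifyCV:
    def make_table(self, auc_like=1.0, seed=0, n_chars=10):
        rng = np.random.default_rng(seed)
        rows = []
        for c in range(n_chars):
            for s in range(11):
                is_target = s in {c % 5, 5 + c % 6}
                value = float(is_target) * auc_like + rng.standard_normal() * (1 - auc_like + 1e-12)
                rows.append({"character_index": c, "stimulus_id": s,
                             "is_target": is_target, "n_trials_averaged": 15,
                             "peak": value})
        return decode.FeatureTable(pd.DataFrame(rows), ("peak",))

    def test_perfectly_separated_features(self):
        table = self.make_table(auc_like=1.0)
        report = decode.classify_cv(table, n_repeats=3, rng_seed=0)
        assert np.allclose(report.results["accuracy_pct"], 100.0)
        assert np.allclose(report.results["auc"], 1.0)

    def test_permuted_labels_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = self.make_table(auc_like=1.0, seed=seed)
            frame = table.frame.copy()
            frame["is_target"] = rng.permutation(frame["is_target"].to_numpy())
            if frame.groupby("character_index")["is_target"].nunique().min() < 2:
                continue
            shuffled = decode.FeatureTable(frame, ("peak",))
            report = decode.classify_cv(shuffled, n_repeats=5, rng_seed=seed)
            aucs.append(report.results["auc"].mean())
        assert abs(np.median(aucs) - 0.5) <= 0.1

    def test_deterministic_under_seed(self):
        table = self.make_table(auc_like=0.7, seed=3)
        a = decode.classify_cv(table, n_repeats=4, rng_seed=9).results
        b = decode.classify_cv(table, n_repeats=4, rng_seed=9).results
        assert a.equals(b)

    def test_single_class_rejected(self):
        table = self.make_table()
        frame = table.frame.copy()
        frame["is_target"] = True
        with pytest.raises(DomainError):
            decode.classify_cv(decode.FeatureTable(frame, ("peak",)))


class TestPredictCharacter:
    def test_argmax_row_and_column(self):
        matrix = default_matrix()  # 5 rows, 6 columns
        row_counts = [3, 1, 9, 2, 0]
        col_counts = [1, 1, 1, 8, 2, 0]
        graphs = {}
        for s, n in enumerate(row_counts + col_counts):
            graphs[s] = graph_with_edges(n, n_ch=6)
        pred = decode.predict_character(graphs, matrix)
        assert (pred.row_id, pred.col_id) == (2, 8)  # row 3, column 4, 1-based
        assert pred.character_index == matrix.character_at(2, 8)
        assert not pred.tie_broken

    def test_all_equal_counts_resolved_deterministically(self):
        matrix = SpellerMatrix(2, 2)
        graphs = {s: graph_with_edges(1, n_ch=4) for s in range(4)}
        pred = decode.predict_character(graphs, matrix)
        assert pred.tie_broken
        assert (pred.row_id, pred.col_id) == (0, 2)

    def test_tie_broken_by_mean_plv(self):
        matrix = SpellerMatrix(2, 2)
        graphs = {
            0: graph_with_edges(2, n_ch=4, mean_plv=0.2),
            1: graph_with_edges(2, n_ch=4, mean_plv=0.9),
            2: graph_with_edges(1, n_ch=4),
            3: graph_with_edges(0, n_ch=4),
        }
        pred = decode.predict_character(graphs, matrix)
        assert pred.row_id == 1
        assert pred.tie_broken

    def test_missing_stimulus_graph_rejected(self):
        with pytest.raises(DomainError):
            decode.predict_character({0: graph_with_edges(1)}, SpellerMatrix(2, 2))


class TestAucVsTrials:
    def test_single_trial_with_plv_feature_rejected(self):
        epochs = speller_epochs(n_chars=4, n_trials_per_set=3)
        with pytest.raises(DomainError, match="at least 2 trials"):
            decode.auc_vs_trials(epochs, {"plv": ("mean_plv",)}, [1, 2],
                                 n_repeats=1)

    def test_trial_count_beyond_available_rejected(self):
        epochs = speller_epochs(n_chars=4, n_trials_per_set=3)
        with pytest.raises(DomainError, match="exceeds"):
            decode.auc_vs_trials(epochs, {"peak": ("peak",)}, [5], n_repeats=1)

    def test_full_trial_count_equals_full_feature_table(self):
        epochs = speller_epochs(n_chars=6, n_trials_per_set=3, separation=2.0)
        report = decode.auc_vs_trials(epochs, {"peak": ("peak",)}, [3],
                                      n_repeats=2, rng_seed=0)
        # k = all trials: subsets are the whole sets, so features equal the
        # full table's and scores are perfect for well-separated data
        full = decode.build_features(epochs, None, ("peak",))
        assert np.allclose(report.results["auc"], 1.0)
        assert len(report.results) == 2
        assert full.frame["peak"].notna().all()


class TestCompareAlgorithms:
    def make_report(self, auc_a, auc_b):
        rows = [
            {"algorithm": name, "n_trials": 15, "repeat": i,
             "accuracy_pct": 50.0, "auc": v}
            for name, values in (("a", auc_a), ("b", auc_b))
            for i, v in enumerate(values)
        ]
        return decode.EvaluationReport(pd.DataFrame(rows), len(auc_a))

    def test_identical_distributions_not_significant(self):
        report = self.make_report(np.linspace(0.5, 0.9, 10),
                                  np.linspace(0.5, 0.9, 10))
        stat, p = decode.compare_algorithms(report, ("a", "b"))
        assert p > 0.9 and abs(stat) < 1e-9

    def test_disjoint_distributions_significant(self):
        report = self.make_report(np.linspace(0.8, 0.9, 10),
                                  np.linspace(0.5, 0.6, 10))
        _, p = decode.compare_algorithms(report, ("a", "b"))
        assert p < 0.001

    def test_insufficient_observations_rejected(self):
        report = self.make_report([0.5, 0.6], [0.7, 0.8])
        with pytest.raises(DomainError):
            decode.compare_algorithms(report, ("a", "b"))


def test_baseline_registry_exposes_pluggable_slots():
    assert {"xdawn", "swlda"} <= set(decode.BASELINE_REGISTRY)
    assert decode.BASELINE_REGISTRY["xdawn"] is None  # not bundled, pluggable
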