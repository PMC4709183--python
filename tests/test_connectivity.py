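"""Phase extraction, PLV, surrogate null, edge significance, contrasts."""

import numpy as np
import pytest

from plvspeller import connectivity as conn
from plvspeller.errors import DegenerateInputError, DomainError
from plvspeller.validation import bruteforce_plv

from conftest import make_epochs

FS = 500.0


def phase_tensor(phases, fs=FS):
    phases = np.asarray(phases, float)
    time_ms = np.arange(phases.shape[-1]) / fs * 1000.0
    return conn.PhaseTensor(phases, time_ms, fs)


class TestInstantaneousPhase:
    def test_cosine_phase_advances_at_carrier_rate(self):
        t = np.arange(0, 2, 1 / FS)
        f = 5.0
        epochs = make_epochs(np.cos(2 * np.pi * f * t)[None, None, :])
        ph = conn.instantaneous_phase(epochs)
        unwrapped = np.unwrap(ph.phases[0, 0])
        k = slice(200, -200)  # away from epoch edges
        slope = np.polyfit(t[k], unwrapped[k], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_sin_vs_cos_quarter_cycle_offset(self):
        t = np.arange(0, 2, 1 / FS)
        data = np.stack([np.cos(2 * np.pi * 6 * t), np.sin(2 * np.pi * 6 * t)])
        ph = conn.instantaneous_phase(make_epochs(data[None]))
        diff = np.angle(np.exp(1j * (ph.phases[0, 0] - ph.phases[0, 1])))
        assert np.allclose(diff[200:-200], np.pi / 2, atol=0.02)

    def test_amplitude_invariance(self):
        t = np.arange(0, 1, 1 / FS)
        x = np.cos(2 * np.pi * 7 * t) + 0.3 * np.sin(2 * np.pi * 3 * t)
        ph1 = conn.instantaneous_phase(make_epochs(x[None, None, :]))
        ph2 = conn.instantaneous_phase(make_epochs(5.0 * x[None, None, :]))
        assert np.allclose(ph1.phases, ph2.phases, atol=1e-10)

    def test_all_zero_signal_rejected(self):
        data = np.ones((2, 2, 100))
        data[1, 0] = 0.0
        with pytest.raises(DegenerateInputError, match="trial 1"):
            conn.instantaneous_phase(make_epochs(data))


class TestPLVTimecourse:
    def test_19_channels_give_171_pairs(self):
        rng = np.random.default_rng(0)
        tc = conn.plv_timecourse(phase_tensor(rng.uniform(-np.pi, np.pi, (3, 19, 4))))
        assert len(tc.pairs) == 171
        assert tc.plv.shape == (171, 4)

    def test_identical_phases_lock_perfectly(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(-np.pi, np.pi, (5, 3, 50))
        phases[:, 2, :] = phases[:, 0, :]
        tc = conn.plv_timecourse(phase_tensor(phases))
        assert np.allclose(tc.plv[tc.pairs.index((0, 2))], 1.0)

    def test_common_phase_offset_still_locks(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(-np.pi, np.pi, (6, 2, 30))
        phases[:, 1, :] = phases[:, 0, :] + 1.2  # constant relative phase
        tc = conn.plv_timecourse(phase_tensor(phases))
        assert np.allclose(tc.plv[0], 1.0)

    def test_adding_common_phase_function_is_invariant(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(-np.pi, np.pi, (6, 2, 40))
        common = rng.uniform(-np.pi, np.pi, (6, 1, 40))
        tc1 = conn.plv_timecourse(phase_tensor(phases))
        tc2 = conn.plv_timecourse(phase_tensor(phases + common))
        assert np.allclose(tc1.plv, tc2.plv, atol=1e-12)

    def test_matches_bruteforce_oracle_to_machine_precision(self):
        rng = np.random.default_rng(4)
        phases = rng.uniform(-np.pi, np.pi, (6, 4, 20))
        tc = conn.plv_timecourse(phase_tensor(phases))
        pairs, oracle = bruteforce_plv(phases)
        assert pairs == tc.pairs
        assert np.abs(tc.plv - oracle).max() < 1e-12

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        tc = conn.plv_timecourse(phase_tensor(rng.uniform(-9, 9, (8, 3, 64))))
        assert np.all(tc.plv >= 0) and np.all(tc.plv <= 1 + 1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(DomainError):
            conn.plv_timecourse(phase_tensor(np.zeros((1, 2, 10))))

    def test_condition_mask_subsets_trials(self):
        rng = np.random.default_rng(6)
        phases = rng.uniform(-np.pi, np.pi, (8, 2, 10))
        mask = np.array([True] * 4 + [False] * 4)
        tc = conn.plv_timecourse(phase_tensor(phases), condition_mask=mask)
        assert tc.n_trials == 4
        ref = conn.plv_timecourse(phase_tensor(phases[:4]))
        assert np.allclose(tc.plv, ref.plv)


class TestWindowAverage:
    def test_constant_plv_gives_constant_weights(self):
        tc = conn.PLVTimeCourse(
            plv=np.full((3, 500), 0.42),
            pairs=[(0, 1), (0, 2), (1, 2)],
            n_trials=5,
            time_ms=-200 + np.arange(500) * 2.0,
            fs=FS,
        )
        g = conn.window_average(tc)
        ii, jj = np.triu_indices(3, k=1)
        assert np.allclose(g.weights[ii, jj], 0.42)
        assert np.allclose(g.weights, g.weights.T)
        assert np.all(np.diag(g.weights) == 0)

    def test_empty_window_rejected(self):
        tc = conn.PLVTimeCourse(np.zeros((1, 10)), [(0, 1)], 3,
                                np.arange(10.0), FS)
        with pytest.raises(DomainError):
            conn.window_average(tc, window_ms=(5000.0, 6000.0))


class TestSurrogates:
    def test_amplitude_spectrum_preserved_exactly(self, tiny_epochs):
        surr = conn.surrogate_epochs(tiny_epochs, rng_seed=3)
        a0 = np.abs(np.fft.rfft(tiny_epochs.data, axis=-1))
        a1 = np.abs(np.fft.rfft(surr.data, axis=-1))
        denom = np.maximum(a0, 1e-12)
        assert (np.abs(a0 - a1) / denom).max() < 1e-6

    def test_surrogates_destroy_perfect_coupling(self):
        rng = np.random.default_rng(7)
        t = np.arange(500) / FS
        common = np.cos(2 * np.pi * 6 * t + rng.uniform(0, 2 * np.pi, (30, 1)))
        data = np.stack([common, common], axis=1) + 0.01 * rng.standard_normal((30, 2, 500))
        epochs = make_epochs(data)
        tc = conn.plv_timecourse(conn.instantaneous_phase(epochs))
        assert conn.window_average(tc).weights[0, 1] > 0.99
        surr = conn.make_surrogates(epochs, n_surrogates=100, rng_seed=1)
        assert surr.plv_surr.mean() < 0.2

    def test_deterministic_under_seed(self, tiny_epochs):
        a = conn.make_surrogates(tiny_epochs, n_surrogates=100, rng_seed=5)
        b = conn.make_surrogates(tiny_epochs, n_surrogates=100, rng_seed=5)
        c = conn.make_surrogates(tiny_epochs, n_surrogates=100, rng_seed=6)
        assert np.array_equal(a.plv_surr, b.plv_surr)
        assert not np.array_equal(a.plv_surr, c.plv_surr)

    def test_too_few_surrogates_for_alpha_rejected(self):
        with pytest.raises(DomainError):
            conn.SurrogateDistribution(
                plv_surr=np.zeros((50, 1)), pairs=[(0, 1)],
                window_ms=(200.0, 500.0), alpha=0.01,
            )

    def test_one_of_pair_mode_runs_and_differs(self, tiny_epochs):
        a = conn.make_surrogates(tiny_epochs, n_surrogates=100, rng_seed=5,
                                 randomize="one_of_pair")
        assert a.plv_surr.shape[1] == len(a.pairs)
        with pytest.raises(DomainError):
            conn.make_surrogates(tiny_epochs, randomize="both?")


class TestSignificantEdges:
    def make_graph_and_surr(self, observed, surr_values):
        n_surr = len(surr_values)
        weights = np.zeros((2, 2))
        weights[0, 1] = weights[1, 0] = observed
        graph = conn.ConnectivityGraph(weights, (200.0, 500.0), 10)
        surr = conn.SurrogateDistribution(
            plv_surr=np.asarray(surr_values, float)[:, None],
            pairs=[(0, 1)], window_ms=(200.0, 500.0), alpha=0.01,
        )
        return graph, surr

    def test_observed_above_all_200_surrogates_is_retained(self):
        graph, surr = self.make_graph_and_surr(0.9, np.linspace(0.1, 0.5, 200))
        out = conn.significant_edges(graph, surr)
        assert out.p_values[0] == pytest.approx(1 / 201)
        assert out.edge_count == 1
        assert out.adjacency[0, 1] and out.adjacency[1, 0]

    def test_observed_below_median_is_rejected(self):
        graph, surr = self.make_graph_and_surr(0.3, np.linspace(0.1, 0.9, 200))
        out = conn.significant_edges(graph, surr)
        assert out.edge_count == 0

    def test_mismatched_pair_sets_rejected(self):
        graph, _ = self.make_graph_and_surr(0.5, np.zeros(200))
        surr = conn.SurrogateDistribution(
            plv_surr=np.zeros((200, 3)), pairs=[(0, 1), (0, 2), (1, 2)],
            window_ms=(200.0, 500.0),
        )
        with pytest.raises(DomainError):
            conn.significant_edges(graph, surr)


class TestMeanPLVFeature:
    def test_uniform_weights(self):
        g = conn.ConnectivityGraph(np.full((4, 4), 0.5) - 0.5 * np.eye(4),
                                   (200.0, 500.0), 5)
        assert conn.mean_plv_feature(g) == pytest.approx(0.5)

    def test_zero_off_diagonal(self):
        g = conn.ConnectivityGraph(np.eye(4) * 0.0, (200.0, 500.0), 5)
        assert conn.mean_plv_feature(g) == 0.0

    def test_invariant_to_channel_relabeling(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0, 1, (5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        perm = rng.permutation(5)
        g1 = conn.ConnectivityGraph(w, (200.0, 500.0), 5)
        g2 = conn.ConnectivityGraph(w[np.ix_(perm, perm)], (200.0, 500.0), 5)
        assert conn.mean_plv_feature(g1) == pytest.approx(conn.mean_plv_feature(g2))


class TestConditionContrast:
    def test_identical_samples_not_significant(self):
        x = list(range(10))
        stat, p = conn.condition_contrast(x, x)
        assert p > 0.9

    def test_fully_separated_samples_highly_significant(self):
        stat, p = conn.condition_contrast(np.arange(10) + 100, np.arange(10))
        assert p < 0.001

    def test_insufficient_observations_rejected(self):
        with pytest.raises(DomainError):
            conn.condition_contrast([1, 2], [3, 4, 5, 6, 7])


class TestPLVBaselineNormalization:
    def test_zscores_against_baseline_segment(self):
        rng = np.random.default_rng(0)
        time_ms = -200 + np.arange(500) * 2.0
        tc = conn.PLVTimeCourse(rng.uniform(0, 1, (3, 500)), [(0, 1), (0, 2), (1, 2)],
                                8, time_ms, FS)
        out = conn.normalize_plv_baseline(tc)
        base = out.plv[:, time_ms < 0]
        assert np.allclose(base.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(base.std(axis=1), 1.0, atol=1e-10)
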