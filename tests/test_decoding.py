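"""Decoding tests: fold assignment counting, pseudo-averaging oracle,
chance-level and separable classification, exhaustive fold-assignment
enumeration, summaries and trial equating."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from tmvpa import (DecodingConfig, assign_folds, decode_timepoint,
                   decode_timeseries, equate_trial_counts, make_pseudotrials,
                   summarize_accuracy)
from tmvpa.decoding import AccuracyTimeSeries
from tmvpa.errors import InsufficientDataError, ParameterError


class TestAssignFolds:
    def test_exact_division(self):
        labels = np.array([0, 1] * 4)
        folds = assign_folds(labels, 4, np.random.default_rng(0))
        for f in range(4):
            assert (labels[folds == f] == 0).sum() == 1
            assert (labels[folds == f] == 1).sum() == 1

    def test_round_robin_remainders(self):
        labels = np.array([0] * 5 + [1] * 5)
        folds = assign_folds(labels, 4, np.random.default_rng(1))
        for cls in (0, 1):
            sizes = sorted(
                (folds[labels == cls] == f).sum() for f in range(4))
            assert sizes == [1, 1, 1, 2]

    def test_deterministic_given_seed(self):
        labels = np.repeat([0, 1], 10)
        a = assign_folds(labels, 4, np.random.default_rng(5))
        b = assign_folds(labels, 4, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_too_few_trials_raises(self):
        with pytest.raises(InsufficientDataError):
            assign_folds(np.array([0, 0, 0, 1, 1, 1]), 4,
                         np.random.default_rng(0))


class TestMakePseudotrials:
    def test_single_trial_fold_is_identity(self):
        x = np.array([[1.0, 2.0], [5.0, 6.0]])
        y = np.array([0, 1])
        xp, yp, fp = make_pseudotrials(x, y, np.array([0, 0]))
        np.testing.assert_array_equal(np.sort(xp, axis=0), np.sort(x, axis=0))

    def test_arithmetic_mean(self):
        x = np.array([[0.0, 0.0], [2.0, 2.0], [9.0, 9.0]])
        y = np.array([0, 0, 1])
        xp, yp, _ = make_pseudotrials(x, y, np.zeros(3, dtype=int))
        np.testing.assert_allclose(xp[yp == 0][0], [1.0, 1.0])

    def test_against_groupby_mean_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 4))
        y = rng.integers(0, 2, 12)
        y[:4] = [0, 0, 1, 1]                       # both classes everywhere
        folds = np.repeat([0, 1, 2], 4)
        xp, yp, fp = make_pseudotrials(x, y, folds)
        df = pd.DataFrame(x)
        df["y"], df["f"] = y, folds
        oracle = df.groupby(["f", "y"]).mean()
        for xrow, yv, fv in zip(xp, yp, fp):
            np.testing.assert_allclose(xrow,
                                       oracle.loc[(fv, yv)].to_numpy())

    def test_empty_cell_raises(self):
        x = np.zeros((4, 2))
        y = np.array([0, 0, 0, 1])
        with pytest.raises(InsufficientDataError):
            make_pseudotrials(x, y, np.array([0, 0, 1, 1]))


class TestDecodeTimepoint:
    def test_chance_level_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 16))
        y = np.repeat([False, True], 100)
        acc, _ = decode_timepoint(x, y, DecodingConfig(n_permutations=30),
                                  rng)
        assert acc == pytest.approx(50.0, abs=3.0)

    def test_separable_classes_are_perfect(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 8)) * 0.01
        y = np.repeat([False, True], 20)
        x[y, 0] += 10.0
        acc, w = decode_timepoint(x, y, DecodingConfig(n_permutations=10),
                                  rng)
        assert acc == 100.0
        assert w[0] > 0                      # oriented toward positive class

    def test_exhaustive_enumeration_oracle(self):
        # 8 trials, 4 folds: every stratified assignment puts one trial
        # of each class per fold, so the space of assignments reduces to
        # the 24 pairings of class-1 trials with class-0 trials (times
        # fold relabelings that do not change CV accuracy).
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 2))
        x[4:, :] += 1.2
        y = np.repeat([False, True], 4)
        accs = []
        for pairing in itertools.permutations(range(4)):
            fold_of = np.empty(8, dtype=int)
            fold_of[:4] = np.arange(4)
            fold_of[4 + np.array(pairing)] = np.arange(4)
            correct = 0
            for f in range(4):
                train = fold_of != f
                clf = SVC(kernel="linear", C=1.0)
                clf.fit(x[train], y[train])
                correct += (clf.predict(x[~train]) == y[~train]).sum()
            accs.append(100.0 * correct / 8)
        oracle = np.mean(accs)
        acc, _ = decode_timepoint(
            x, y, DecodingConfig(n_permutations=300), np.random.default_rng(7))
        assert acc == pytest.approx(oracle, abs=2.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 6))
        y = np.repeat([False, True], 30)
        x[y] += 0.8
        cfg = DecodingConfig(n_permutations=40)
        a1, _ = decode_timepoint(x, y, cfg, np.random.default_rng(0))
        a2, _ = decode_timepoint(x, ~y, cfg, np.random.default_rng(0))
        assert a1 == pytest.approx(a2, abs=3.0)

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(24, 5))
        y = np.repeat([False, True], 12)
        x[y, 2] += 1.0
        cfg = DecodingConfig(n_permutations=5)
        perm = np.array([3, 1, 4, 0, 2])
        a1, w1 = decode_timepoint(x, y, cfg, np.random.default_rng(9))
        a2, w2 = decode_timepoint(x[:, perm], y, cfg,
                                  np.random.default_rng(9))
        assert a1 == a2
        np.testing.assert_allclose(w2, w1[perm], atol=1e-10)

    def test_degenerate_training_warns_and_scores_chance(self):
        x = np.ones((8, 3))
        y = np.repeat([False, True], 4)
        with pytest.warns(UserWarning, match="degenerate"):
            acc, w = decode_timepoint(
                x, y, DecodingConfig(n_permutations=2),
                np.random.default_rng(0))
        assert acc == 50.0
        np.testing.assert_array_equal(w, 0.0)


class TestDecodeTimeseries:
    def test_deterministic_under_seed(self, make_epochs):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(24, 34, 30))
        epochs = make_epochs(data, units="z")
        cfg = DecodingConfig(n_permutations=3, seed=42)
        a = decode_timeseries(epochs, "location", cfg)
        b = decode_timeseries(epochs, "location", cfg)
        np.testing.assert_array_equal(a.accuracy_pct, b.accuracy_pct)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_post_onset_restriction(self, make_epochs):
        data = np.random.default_rng(1).normal(size=(16, 34, 30))
        epochs = make_epochs(data, units="z")     # times -100.. at 500 Hz
        ts = decode_timeseries(epochs, "location",
                               DecodingConfig(n_permutations=1, seed=0))
        assert (ts.times >= 0).all()

    def test_too_few_trials_per_class_raises(self, make_epochs):
        data = np.zeros((6, 34, 10))
        epochs = make_epochs(data, units="z")
        with pytest.raises(InsufficientDataError):
            decode_timeseries(epochs, "location", DecodingConfig(seed=0))


class TestSummarizeAccuracy:
    def _ts(self, times, accs):
        return AccuracyTimeSeries(
            times=np.asarray(times, dtype=float),
            accuracy_pct=np.asarray(accs, dtype=float),
            weights=np.zeros((len(times), 32)), subject="s", condition="c")

    def test_flat_series(self):
        ts = self._ts([0, 100, 200, 300], [50] * 4)
        s = summarize_accuracy(ts, (100, 300))
        assert (s.peak_accuracy_pct, s.peak_latency_ms,
                s.window_mean_pct) == (50.0, 0.0, 50.0)

    def test_single_spike(self):
        times = np.arange(0, 500, 2.0)
        accs = np.full(len(times), 50.0)
        accs[times == 264] = 90.0
        s = summarize_accuracy(self._ts(times, accs), (200, 350))
        assert s.peak_accuracy_pct == 90.0 and s.peak_latency_ms == 264.0

    def test_hand_made_five_points(self):
        ts = self._ts([-50, 0, 50, 100, 150], [80, 55, 70, 70, 60])
        s = summarize_accuracy(ts, (50, 150))
        assert s.peak_accuracy_pct == 70.0
        assert s.peak_latency_ms == 50.0          # earliest maximum, post-onset
        assert s.window_mean_pct == pytest.approx((70 + 70 + 60) / 3)

    def test_peak_ignores_preonset(self):
        ts = self._ts([-50, 0, 50], [99, 60, 61])
        s = summarize_accuracy(ts, (0, 50))
        assert s.peak_accuracy_pct == 61.0

    def test_empty_window_raises(self):
        with pytest.raises(ParameterError):
            summarize_accuracy(self._ts([0, 10], [50, 50]), (400, 500))


class TestEquateTrialCounts:
    def test_min_rule(self, make_epochs):
        cells = {}
        for name, n in [("a", 30), ("b", 28), ("c", 31), ("d", 28)]:
            cells[name] = make_epochs(np.zeros((n, 34, 5)))
        out = equate_trial_counts(cells, np.random.default_rng(0))
        assert {k: v.n_trials for k, v in out.items()} == {
            "a": 28, "b": 28, "c": 28, "d": 28}

    def test_already_equal_identity(self, make_epochs):
        cells = {k: make_epochs(np.zeros((5, 34, 5))) for k in "ab"}
        out = equate_trial_counts(cells, np.random.default_rng(0))
        assert all(v.n_trials == 5 for v in out.values())

    def test_deterministic_given_seed(self, make_epochs):
        rng_data = np.random.default_rng(1).normal(size=(12, 34, 5))
        cells = {"a": make_epochs(rng_data), "b": make_epochs(rng_data[:7])}
        out1 = equate_trial_counts(cells, np.random.default_rng(3))
        out2 = equate_trial_counts(cells, np.random.default_rng(3))
        np.testing.assert_array_equal(out1["a"].data, out2["a"].data)
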