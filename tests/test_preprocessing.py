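"""Preprocessing oracles: threshold semantics, exhaustive-scan rejection,
convolution smoothing, baseline z-scoring conventions, N2pc arithmetic."""

import numpy as np
import pytest

from tmvpa import (RejectionCriteria, baseline_zscore, n2pc_difference,
                   reject_artifacts, running_average, select_valid_trials)
from tmvpa.errors import ParameterError, SchemaError, UnitsError


def _zeros(n_trials, n_samples=50):
    return np.zeros((n_trials, 34, n_samples))


class TestRejectArtifacts:
    def test_heog_over_threshold_rejected(self, make_epochs, montage):
        data = _zeros(1)
        data[0, montage.index("HEOG"), 10] = 26.0
        kept, log = reject_artifacts(make_epochs(data))
        assert kept.n_trials == 0 and log.counts["heog"] == 1

    def test_exactly_at_threshold_kept(self, make_epochs, montage):
        data = _zeros(1)
        data[0, montage.index("HEOG"), 10] = 25.0
        data[0, montage.index("VEOG"), 11] = 60.0
        data[0, montage.index("Pz"), 12] = 80.0
        kept, _ = reject_artifacts(make_epochs(data))
        assert kept.n_trials == 1

    def test_all_zero_kept(self, make_epochs):
        kept, log = reject_artifacts(make_epochs(_zeros(3)))
        assert kept.n_trials == 3 and log.n_rejected == 0

    def test_against_exhaustive_scan_oracle(self, make_epochs, montage):
        # 10 trials, 3 violators (one per criterion); oracle scans every
        # sample of every channel against its role threshold.
        rng = np.random.default_rng(7)
        data = rng.normal(0, 3, size=(10, 34, 50))
        data[2, montage.index("HEOG"), 5] = -30.0
        data[5, montage.index("VEOG"), 8] = 70.0
        data[8, montage.index("Cz"), 30] = 90.0
        epochs = make_epochs(data)
        crit = RejectionCriteria()
        thresholds = {"heog": 25.0, "veog": 60.0, "scalp": 80.0}
        expected_kept = []
        for tr in range(10):
            ok = True
            for ci, name in enumerate(montage.names):
                thr = thresholds[montage.roles[name]]
                if np.any(np.abs(data[tr, ci]) > thr):
                    ok = False
            expected_kept.append(ok)
        kept, log = reject_artifacts(epochs, crit)
        assert kept.n_trials == sum(expected_kept) == 7
        assert log.table["kept"].tolist() == expected_kept
        assert log.n_kept + log.n_rejected == 10

    def test_z_scored_input_rejected(self, make_epochs):
        epochs = make_epochs(_zeros(2), units="z")
        with pytest.raises(UnitsError):
            reject_artifacts(epochs)

    def test_monotone_in_thresholds(self, make_epochs):
        rng = np.random.default_rng(3)
        epochs = make_epochs(rng.normal(0, 20, size=(30, 34, 40)))
        tight, _ = reject_artifacts(epochs, RejectionCriteria(10, 20, 30))
        loose, _ = reject_artifacts(epochs, RejectionCriteria(15, 40, 60))
        assert set(tight.events.trial) <= set(loose.events.trial)


class TestSelectValidTrials:
    def test_mixed_table_row_filter_oracle(self, make_epochs):
        data = np.arange(6 * 34 * 10, dtype=float).reshape(6, 34, 10) % 7
        epochs = make_epochs(
            data, correct=[True, False, True, True, False, True],
            sides=["left", "right", None, "right", "left", "left"])
        out = select_valid_trials(epochs)
        expected = epochs.events.query(
            "correct and target_side in ['left', 'right']")
        assert out.events.trial.tolist() == expected.trial.tolist() == [0, 3, 5]
        np.testing.assert_array_equal(out.data, data[[0, 3, 5]])

    def test_all_valid_is_identity(self, make_epochs):
        epochs = make_epochs(_zeros(4))
        out = select_valid_trials(epochs)
        assert out.n_trials == 4

    def test_all_incorrect_warns_and_empties(self, make_epochs):
        epochs = make_epochs(_zeros(3), correct=[False] * 3)
        with pytest.warns(UserWarning, match="no valid trials"):
            out = select_valid_trials(epochs)
        assert out.n_trials == 0

    def test_missing_column_raises(self, make_epochs):
        epochs = make_epochs(_zeros(2))
        epochs.events = epochs.events.drop(columns=["correct"])
        with pytest.raises(SchemaError):
            select_valid_trials(epochs)


class TestRunningAverage:
    def test_constant_signal_unchanged(self, make_epochs):
        epochs = make_epochs(np.full((2, 34, 60), 3.7))
        out = running_average(epochs, 20.0)
        np.testing.assert_allclose(out.data, 3.7)

    def test_impulse_spreads_to_eleven_samples(self, make_epochs):
        # 500 Hz, 20 ms window -> 11 samples; direct convolution oracle.
        data = _zeros(1, 60)
        data[0, 0, 30] = 1.0
        out = running_average(make_epochs(data), 20.0)
        expected = np.zeros(60)
        expected[25:36] = 1.0 / 11.0
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-12)

    def test_truncated_edge_window(self, make_epochs):
        data = _zeros(1, 60)
        data[0, 0, 0] = 1.0
        out = running_average(make_epochs(data), 20.0)
        # at sample k near the left edge the window holds k+6 samples
        for k in range(6):
            assert out.data[0, 0, k] == pytest.approx(1.0 / (k + 6))

    def test_linearity(self, make_epochs):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 3, 34, 50))
        a, b = 2.0, -0.7
        sm = lambda d: running_average(make_epochs(d), 20.0).data
        np.testing.assert_allclose(sm(a * x + b * y), a * sm(x) + b * sm(y),
                                   atol=1e-10)

    def test_white_noise_variance_reduced(self, make_epochs):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 34, 100))
        out = running_average(make_epochs(data), 20.0)
        assert out.data.var() < data.var()

    def test_window_shorter_than_sample_raises(self, make_epochs):
        with pytest.raises(ParameterError):
            running_average(make_epochs(_zeros(1)), 1.0)


class TestBaselineZscore:
    def test_plus_minus_one_baseline(self, make_epochs):
        # baseline samples {-1, +1}: mean 0, population SD 1 -> post-onset
        # values pass through unchanged.
        data = _zeros(1, 60)
        data[0, :, :50] = np.tile([-1.0, 1.0], 25)   # baseline: t < 0
        data[0, 5, 50:] = 4.0
        epochs = make_epochs(data, sfreq=500.0, t_start=-100.0)
        out = baseline_zscore(epochs, (-100.0, -2.0))
        np.testing.assert_allclose(out.data[0, 5, 50:], 4.0)
        assert out.units == "z"

    def test_constant_baseline_trial_excluded(self, make_epochs):
        data = np.ones((2, 34, 60))
        data[1] += np.random.default_rng(0).normal(size=(34, 60))
        out = baseline_zscore(make_epochs(data), (-100.0, 0.0))
        assert out.n_trials == 1
        assert any(p.get("excluded_zero_sd_trials") == 1
                   for p in out.provenance if isinstance(p, dict))

    def test_idempotent_on_baseline_moments(self, make_epochs):
        rng = np.random.default_rng(5)
        epochs = make_epochs(rng.normal(2, 3, size=(4, 34, 60)))
        once = baseline_zscore(epochs, (-100.0, 0.0))
        mask = once.times <= 0
        base = once.data[:, :, mask]
        np.testing.assert_allclose(base.mean(axis=2), 0.0, atol=1e-10)
        np.testing.assert_allclose(base.std(axis=2), 1.0, atol=1e-10)

    def test_too_few_baseline_samples_raises(self, make_epochs):
        with pytest.raises(ParameterError):
            baseline_zscore(make_epochs(_zeros(1)), (-100.0, -99.9))


class TestN2pc:
    def test_left_target_contribution(self, make_epochs, montage):
        data = _zeros(1, 10)
        data[0, montage.index("PO8"), :] = -2.0     # contralateral to left
        wave = n2pc_difference(make_epochs(data, sides=["left"]))
        np.testing.assert_allclose(wave.to_numpy(), -2.0)

    def test_equal_activity_gives_zero(self, make_epochs, montage):
        data = _zeros(4, 10)
        data[:, montage.index("PO7"), :] = 1.3
        data[:, montage.index("PO8"), :] = 1.3
        wave = n2pc_difference(make_epochs(data))
        np.testing.assert_allclose(wave.to_numpy(), 0.0)

    def test_two_trial_hand_computation(self, make_epochs, montage):
        data = _zeros(2, 4)
        po7, po8 = montage.index("PO7"), montage.index("PO8")
        data[0, po7], data[0, po8] = 1.0, 3.0    # left target: contra=PO8
        data[1, po7], data[1, po8] = 2.0, -1.0   # right target: contra=PO7
        wave = n2pc_difference(make_epochs(data, sides=["left", "right"]))
        # trial 0: 3-1 = 2; trial 1: 2-(-1) = 3; mean = 2.5
        np.testing.assert_allclose(wave.to_numpy(), 2.5)

    def test_antisymmetry_under_swap_and_flip(self, make_epochs, montage):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(6, 34, 12))
        sides = ["left", "right", "left", "right", "left", "right"]
        wave = n2pc_difference(make_epochs(data, sides=sides))
        po7, po8 = montage.index("PO7"), montage.index("PO8")
        swapped = data.copy()
        swapped[:, [po7, po8]] = data[:, [po8, po7]]
        # channel swap alone negates the waveform ...
        wave_swap = n2pc_difference(make_epochs(swapped, sides=sides))
        np.testing.assert_allclose(wave_swap.to_numpy(), -wave.to_numpy())
        # ... and flipping sides too restores it
        flipped = ["right" if s == "left" else "left" for s in sides]
        wave2 = n2pc_difference(make_epochs(swapped, sides=flipped))
        np.testing.assert_allclose(wave2.to_numpy(), wave.to_numpy())

    def test_missing_channel_raises(self, make_epochs):
        with pytest.raises(SchemaError):
            n2pc_difference(make_epochs(_zeros(1)), left_channel="XX")
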