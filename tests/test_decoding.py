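"""Decoding machinery: window grid, pseudo-trials, channel selection, LOO SVM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.svm import SVC

import serialdep as sd
from serialdep import decoding as dec
from serialdep.epochs import EpochSet


def toy_epochs(data, fs=250.0, t0=-200.0, past=None):
    n, _, nt = data.shape
    time = t0 + 1000.0 / fs * np.arange(nt)
    meta = pd.DataFrame({"trial": np.arange(n),
                         "past_numerosity": past if past is not None
                         else np.resize([12.0, 24.0], n)})
    return EpochSet(data=data, time_ms=time, sampling_rate=fs, trial_meta=meta)


class TestWindowGrid:
    def test_standard_epoch_gives_41_windows(self):
        ep = toy_epochs(np.zeros((2, 3, 226)))
        grid = dec.WindowGrid.for_epochs(ep, length=100, step=20)
        assert grid.n_windows == 41
        assert grid.starts[0] == -200.0 and grid.starts[-1] == 600.0
        np.testing.assert_allclose(np.diff(grid.starts), 20.0)

    def test_constant_epoch_windowed_mean(self):
        ep = toy_epochs(np.full((4, 3, 226), 2.5))
        grid = dec.WindowGrid.for_epochs(ep)
        feats = dec.window_average(ep, grid)
        np.testing.assert_allclose(feats, 2.5)

    def test_single_sample_windows_are_identity(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 2, 26))
        ep = toy_epochs(data, t0=-100.0)
        grid = dec.WindowGrid.for_epochs(ep, length=4.0, step=4.0)
        feats = dec.window_average(ep, grid)
        np.testing.assert_allclose(feats, data[:, :, :grid.n_windows])


class TestPseudoTrials:
    def test_k1_is_permutation_of_trials(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 3))
        P = dec.make_pseudotrials(X, k=1, seed=5)
        assert sorted(map(tuple, P)) == sorted(map(tuple, X))

    def test_groups_average_their_members(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        P = dec.make_pseudotrials(X, k=10, seed=6)
        assert P.shape == (4, 2)
        # independent reconstruction of the seeded partition
        perm = np.random.default_rng(6).permutation(40)
        expected = X[perm[:40].reshape(4, 10)].mean(axis=1)
        np.testing.assert_allclose(P, expected)

    def test_remainder_discarded(self):
        X = np.arange(39, dtype=float)[:, None]
        P = dec.make_pseudotrials(X, k=10, seed=7)
        assert P.shape == (3, 1)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            dec.make_pseudotrials(np.zeros((5, 2)), k=10)


class TestChannelSelection:
    def test_informative_channels_found(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        y = np.repeat([0, 1], 30)
        X[y == 1, 3] += 3.0
        X[y == 1, 7] += 3.0
        sel = dec.select_channels(X, y, n_keep=2)
        assert set(sel) == {3, 7}

    def test_f_ranking_matches_scipy(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 6))
        y = np.repeat([0, 1], 12)
        ours = dec.anova_f_scores(X, y)
        ref = np.array([sps.f_oneway(X[y == 0, c], X[y == 1, c]).statistic
                        for c in range(6)])
        np.testing.assert_allclose(ours, ref)

    def test_select_all_is_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 5))
        y = np.repeat([0, 1], 5)
        np.testing.assert_array_equal(dec.select_channels(X, y, 5), np.arange(5))

    def test_tie_break_prefers_lower_index(self):
        X = np.zeros((8, 4))
        y = np.repeat([0, 1], 4)
        np.testing.assert_array_equal(dec.select_channels(X, y, 2), [0, 1])


class TestSortEpochs:
    def test_balanced_classes(self, signal_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        assert ep0.n_trials == ep1.n_trials
        assert set(ep0.trial_meta["past_numerosity"]) == {12.0}
        assert set(ep1.trial_meta["past_numerosity"]) == {24.0}

    def test_intermediate_past_level_excluded(self):
        past = np.array([12.0, 16.0, 24.0, 12.0, 16.0, 24.0, np.nan, 24.0])
        ep = toy_epochs(np.zeros((8, 2, 26)), past=past)
        ep0, ep1 = sd.sort_epochs_by_past(ep, "numerosity")
        assert ep0.n_trials == 2 and ep1.n_trials == 3

    def test_missing_dimension_rejected(self):
        ep = toy_epochs(np.zeros((4, 2, 26)))  # only past_numerosity labels
        with pytest.raises(ValueError, match="duration"):
            sd.sort_epochs_by_past(ep, "duration")


FAST = dec.DecodingParams(pseudo_k=4, n_pseudo=8, n_iterations=2, seed=17)


class TestDecode:
    def test_signal_recovered_where_injected(self, signal_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        res = sd.decode_timecourse(ep0, ep1, params=FAST)
        assert sd.window_mean_ca(res, 100, 250) > 0.95
        assert abs(sd.window_mean_ca(res, -100, 0) - 0.5) < 0.2

    def test_centroid_oracle_agrees_on_strong_signal(self, signal_epochs):
        # Independent check: a nearest-class-centroid classifier on the same
        # windowed features separates the classes in the signal window.
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        grid = dec.WindowGrid.for_epochs(ep0)
        w = int(np.where(grid.starts == 120.0)[0][0])
        F0 = dec.window_average(ep0, grid)[:, :, w]
        F1 = dec.window_average(ep1, grid)[:, :, w]
        correct = 0
        for i in range(F0.shape[0]):
            c0 = np.delete(F0, i, axis=0).mean(0)
            c1 = F1.mean(0)
            correct += (np.linalg.norm(F0[i] - c0) < np.linalg.norm(F0[i] - c1))
        assert correct / F0.shape[0] > 0.9

    def test_no_signal_is_chance(self, null_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(null_epochs, "numerosity")
        res = sd.decode_timecourse(ep0, ep1, params=FAST)
        sem = res.per_iteration.mean(axis=1).std(ddof=1) / np.sqrt(res.n_iterations)
        assert abs(res.ca.mean() - 0.5) < max(3 * sem, 0.1)

    def test_seeded_determinism(self, signal_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        a = sd.decode_timecourse(ep0, ep1, params=FAST)
        b = sd.decode_timecourse(ep0, ep1, params=FAST)
        np.testing.assert_array_equal(a.per_iteration, b.per_iteration)

    def test_too_few_pseudotrials_rejected(self, signal_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        bad = dec.DecodingParams(pseudo_k=40, n_pseudo=10, n_iterations=1)
        with pytest.raises(ValueError, match="pseudo"):
            sd.decode_timecourse(ep0, ep1, params=bad)

    def test_channel_selection_sees_training_folds_only(self, signal_epochs,
                                                        monkeypatch):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        seen = []
        orig = dec.select_channels

        def spy(X, y, n_keep):
            seen.append(X.shape[0])
            return orig(X, y, n_keep)

        monkeypatch.setattr(dec, "select_channels", spy)
        sd.decode_timecourse(ep0, ep1, params=FAST)
        # training folds hold n_pseudo - 1 pseudo-trials per class
        assert seen and all(n == 2 * (FAST.n_pseudo - 1) for n in seen)

    def test_loo_matches_hand_enumerated_cross_validation(self, signal_epochs):
        """Exhaustive re-implementation of one iteration on a tiny instance."""
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        ep0, ep1 = ep0.subset(np.arange(8)), ep1.subset(np.arange(8))
        params = dec.DecodingParams(pseudo_k=2, n_pseudo=4, n_iterations=1,
                                    n_keep=2, seed=123)
        res = sd.decode_timecourse(ep0, ep1, params=params)

        grid = res.grid
        F0 = dec.window_average(ep0, grid)
        F1 = dec.window_average(ep1, grid)
        rng = np.random.default_rng(params.seed + 0)  # iteration 0
        P = []
        for F in (F0, F1):
            perm = rng.permutation(F.shape[0])
            P.append(F[perm[:8].reshape(4, 2)].mean(axis=1))
        P0, P1 = P
        expected = np.zeros(grid.n_windows)
        for f in range(4):
            tr = [i for i in range(4) if i != f]
            Xtr_all = np.concatenate([P0[tr], P1[tr]])
            ytr = np.repeat([0, 1], 3)
            for w in range(grid.n_windows):
                Xtr = Xtr_all[:, :, w]
                F_scores = np.array([sps.f_oneway(Xtr[ytr == 0, c],
                                                  Xtr[ytr == 1, c]).statistic
                                     for c in range(Xtr.shape[1])])
                F_scores = np.nan_to_num(F_scores)
                sel = np.sort(np.lexsort((np.arange(F_scores.size),
                                          -F_scores))[:2])
                mu, sdv = Xtr[:, sel].mean(0), Xtr[:, sel].std(0)
                sdv[sdv == 0] = 1.0
                clf = SVC(kernel="linear", C=1.0)
                clf.fit((Xtr[:, sel] - mu) / sdv, ytr)
                pred0 = clf.predict((P0[f, sel, w][None] - mu) / sdv)
                pred1 = clf.predict((P1[f, sel, w][None] - mu) / sdv)
                expected[w] += int(pred0[0] == 0) + int(pred1[0] == 1)
        expected /= 8.0
        np.testing.assert_allclose(res.ca, expected)


class TestNullDecode:
    def test_shuffled_labels_destroy_strong_signal(self, signal_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        actual = sd.decode_timecourse(ep0, ep1, params=FAST)
        null = sd.null_decode_timecourse(ep0, ep1, params=FAST)
        assert sd.window_mean_ca(actual, 100, 250) > 0.95
        assert abs(sd.window_mean_ca(null, 100, 250) - 0.5) < 0.25
        assert abs(null.ca.mean() - 0.5) < 0.1

    def test_null_is_deterministic_and_flagged(self, null_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(null_epochs, "numerosity")
        a = sd.null_decode_timecourse(ep0, ep1, params=FAST)
        b = sd.null_decode_timecourse(ep0, ep1, params=FAST)
        assert a.is_null
        np.testing.assert_array_equal(a.per_iteration, b.per_iteration)


class TestTemporalGeneralization:
    def test_diagonal_equals_timecourse(self, signal_epochs):
        ep0, ep1 = sd.sort_epochs_by_past(signal_epochs, "numerosity")
        res = sd.decode_timecourse(ep0, ep1, params=FAST)
        tg = sd.temporal_generalization(ep0, ep1, params=FAST)
        np.testing.assert_allclose(tg.diagonal, res.ca)

    def test_sustained_pattern_generalizes_off_diagonal(self, short_eeg):
        import dataclasses
        eeg = dataclasses.replace(
            short_eeg, signal_windows=((-100.0, 300.0, {"numerosity": 1.0}),))
        table = sd.generate_design_exp1("numerosity", 2, seed=77)
        ep = sd.simulate_epochs(table.iloc[:80], eeg, subject_amplitude=2.0)
        ep0, ep1 = sd.sort_epochs_by_past(ep, "numerosity")
        tg = sd.temporal_generalization(ep0, ep1, params=FAST)
        assert tg.ca.min() > 0.8  # static pattern decodes across all pairs


class TestWindowMeanCA:
    def make_result(self, ca):
        grid = dec.WindowGrid(starts=-200.0 + 20.0 * np.arange(41))
        return dec.DecodingResult(ca=ca, per_iteration=ca[None], grid=grid,
                                  is_null=False, pseudo_k=1, n_pseudo=2,
                                  n_iterations=1, n_keep=1, seed=0)

    def test_constant_ca_any_interval(self):
        res = self.make_result(np.full(41, 0.6))
        assert sd.window_mean_ca(res, 50, 200) == pytest.approx(0.6)

    def test_full_containment_window_selection(self):
        ca = np.zeros(41)
        res = self.make_result(ca)
        grid = res.grid
        qualifying = (grid.starts >= 50) & (grid.starts + 100 <= 200)
        assert list(grid.starts[qualifying]) == [60.0, 80.0, 100.0]
        ca[qualifying] = 1.0
        assert sd.window_mean_ca(res, 50, 200) == pytest.approx(1.0)

    def test_interval_shorter_than_window_rejected(self):
        res = self.make_result(np.full(41, 0.5))
        with pytest.raises(ValueError, match="window"):
            sd.window_mean_ca(res, 0, 50)
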