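"""Population decoding: calibration, balancing, separability, time bins."""

import numpy as np
import pandas as pd
import pytest

from barrelpop.decode import (FeatureMatrix, build_features, decode_binary,
                              decode_time, decode_timecourse, separability,
                              single_cell_decode, subsample_curve,
                              subset_cells, trial_filter)
from barrelpop.session import AnalysisWindow
from barrelpop.signals import TransientTrain


def make_train(onsets, n_frames=10 ** 6):
    onsets = np.asarray(sorted(onsets), dtype=np.int64)
    return TransientTrain(events=np.stack([onsets, onsets + 1], 1),
                          threshold=0.0)


class TestFeatures:
    def test_bin_counting(self, small_session, window):
        sess, _ = small_session
        sf = int(sess.trials["start_frame"].iloc[0])
        pre = window.pre_frames(sess.frame_rate)
        train = make_train([sf - pre + 3, sf - pre + 12])
        feats = build_features([train], sess, mode="time_bins", window=window)
        first = feats.meta["trial"] == 0
        counts = feats.X[first.to_numpy(), 0]
        assert counts[0] == 1 and counts[1] == 1 and counts[2:].sum() == 0

    def test_empty_trains_zero_matrix(self, small_session):
        sess, _ = small_session
        feats = build_features([make_train([])] * 3, sess)
        assert not feats.X.any()

    def test_counts_match_brute_force(self, small_session, window):
        sess, _ = small_session
        rng = np.random.default_rng(0)
        trains = [make_train(rng.choice(sess.n_frames, 200, replace=False))
                  for _ in range(4)]
        feats = build_features(trains, sess, feature_window=(0.0, 4.0))
        starts = sess.trials["start_frame"].to_numpy()
        for c, tr in enumerate(trains):
            for i, sf in enumerate(starts):
                want = sum(1 for o in tr.onsets if sf <= o < sf + 120)
                assert feats.X[i, c] == want


class TestBinaryDecode:
    def test_perfectly_informative_cell(self):
        rng = np.random.default_rng(1)
        y = rng.random(80) < 0.5
        X = y[:, None].astype(float)
        res = decode_binary(X, y, seed=2)
        assert res.accuracy == 1.0

    def test_chance_calibration(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(1.0, (180, 30)).astype(float)
        y = rng.random(180) < 0.5
        res = decode_binary(X, y, n_shuffle=50, seed=4)
        assert 0.45 <= np.mean(res.null_accuracies) <= 0.55
        lo, hi = res.null_interval_99
        assert lo <= res.accuracy <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decode_binary(np.zeros((10, 2)), np.ones(10, dtype=bool))

    def test_subsample_balances_counts(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([np.ones(120, dtype=bool), np.zeros(60, dtype=bool)])
        X = rng.normal(0, 1, (180, 5))
        res = decode_binary(X, y, balance="subsample", seed=6)
        assert len(res.labels) == 120
        assert res.labels.sum() == 60

    def test_weight_balancing_runs(self):
        rng = np.random.default_rng(7)
        y = rng.random(100) < 0.5
        groups = np.where(y, "hit", "correct_rejection")
        groups[:5] = "miss"
        X = rng.normal(0, 1, (100, 8)) + y[:, None]
        res = decode_binary(X, y, balance="weight", weight_groups=groups,
                            seed=8)
        assert res.balance == "weight"
        assert 0.5 < res.accuracy <= 1.0

    def test_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (60, 10))
        y = rng.random(60) < 0.5
        a = decode_binary(X, y, n_shuffle=10, seed=11)
        b = decode_binary(X, y, n_shuffle=10, seed=11)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.null_accuracies, b.null_accuracies)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)


class TestSeparability:
    def test_identical_distributions_zero(self):
        p = np.concatenate([np.arange(10), np.arange(10)])
        lab = np.repeat([0, 1], 10)
        assert separability(p, lab) == 0.0

    def test_point_masses(self):
        p = np.array([0.0, 0.0, 3.0, 3.0])
        lab = np.array([0, 0, 1, 1])
        assert separability(p, lab) == pytest.approx(3.0)

    def test_shifted_pair(self):
        p = np.array([0.0, 1.0, 1.0, 2.0])
        lab = np.array([0, 0, 1, 1])
        assert separability(p, lab) == pytest.approx(1.0)

    def test_effect_size_monotonicity(self):
        rng = np.random.default_rng(12)
        y = rng.random(120) < 0.5
        accs, emds = [], []
        for effect in (0.3, 2.0):
            X = rng.normal(0, 1, (120, 20))
            X[y] += effect / np.sqrt(20)
            res = decode_binary(X, y, seed=13)
            accs.append(res.accuracy)
            emds.append(res.separability)
        assert accs[1] > accs[0]
        assert emds[1] > emds[0]


class TestTimecourse:
    def _features(self, informative_bin, n_trials=48, n_bins=6, seed=0):
        rng = np.random.default_rng(seed)
        y = np.tile([True, False], n_trials // 2)
        X = rng.poisson(0.3, (n_trials * n_bins, 8)).astype(float)
        meta = pd.DataFrame({"trial": np.repeat(np.arange(n_trials), n_bins),
                             "bin": np.tile(np.arange(n_bins), n_trials),
                             "time_s": np.tile(np.arange(n_bins) / 3.0,
                                               n_trials)})
        if informative_bin is not None:
            sel = meta["bin"].to_numpy() == informative_bin
            X[sel, 0] += 20 * y[meta.loc[sel, "trial"]]
        return FeatureMatrix(X=X, meta=meta), dict(enumerate(y))

    def test_single_informative_bin(self):
        feats, labels = self._features(informative_bin=3)
        res = decode_timecourse(feats, labels, n_shuffle=60, seed=1)
        assert res.significant[3]
        assert res.first_significant_bin == 3
        assert res.significant.sum() <= 2   # at most one false positive here

    def test_no_signal_no_first_bin(self):
        feats, labels = self._features(informative_bin=None, seed=5)
        res = decode_timecourse(feats, labels, n_shuffle=60, seed=2)
        assert res.significant.sum() <= 1


class TestTimeDecode:
    def test_identity_confusion_unique_cells(self):
        n_bins, n_trials = 18, 16
        X = np.zeros((n_trials * n_bins, n_bins))
        meta = pd.DataFrame({"trial": np.repeat(np.arange(n_trials), n_bins),
                             "bin": np.tile(np.arange(n_bins), n_trials),
                             "time_s": 0.0})
        X[np.arange(len(meta)), meta["bin"]] = 1.0
        feats = FeatureMatrix(X=X, meta=meta)
        res = decode_time(feats, np.arange(n_trials), seed=3)
        assert np.allclose(res.confusion, np.eye(n_bins))
        assert res.mean_abs_error_bins == 0.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(14)
        n_bins, n_trials = 6, 20
        X = rng.poisson(0.5, (n_trials * n_bins, 10)).astype(float)
        meta = pd.DataFrame({"trial": np.repeat(np.arange(n_trials), n_bins),
                             "bin": np.tile(np.arange(n_bins), n_trials),
                             "time_s": 0.0})
        res = decode_time(FeatureMatrix(X=X, meta=meta),
                          np.arange(n_trials), seed=4)
        assert np.allclose(np.nansum(res.confusion, axis=1), 1.0)

    def test_unstructured_population_near_uniform(self):
        rng = np.random.default_rng(15)
        n_bins, n_trials = 6, 60
        X = rng.poisson(1.0, (n_trials * n_bins, 12)).astype(float)
        meta = pd.DataFrame({"trial": np.repeat(np.arange(n_trials), n_bins),
                             "bin": np.tile(np.arange(n_bins), n_trials),
                             "time_s": 0.0})
        res = decode_time(FeatureMatrix(X=X, meta=meta),
                          np.arange(n_trials), seed=5)
        # with no temporal structure every true bin should be classified the
        # same way: rows agree with the overall predicted marginal up to
        # multinomial noise (the marginal itself carries the classifier's
        # finite-sample bin preferences)
        marginal = res.confusion.mean(axis=0)
        se = np.sqrt(np.maximum(marginal * (1 - marginal), 1e-4) / n_trials)
        assert np.abs(res.confusion - marginal).max() < 4.5 * np.max(se)
        assert np.abs(np.diag(res.confusion) - 1 / n_bins).max() < 0.15

    def test_cross_condition_evaluation(self):
        n_bins = 4
        tr_trials, te_trials = np.arange(12), np.arange(12, 18)
        rows = []
        X = []
        for t in range(18):
            for b in range(n_bins):
                feat = np.zeros(n_bins)
                feat[b] = 1.0
                X.append(feat)
                rows.append(dict(trial=t, bin=b, time_s=0.0))
        feats = FeatureMatrix(X=np.array(X), meta=pd.DataFrame(rows))
        res = decode_time(feats, tr_trials, te_trials, seed=6)
        assert np.allclose(res.confusion, np.eye(n_bins))
        assert res.row_support.sum() == 6 * n_bins


class TestAuxiliary:
    def _data(self, seed=16):
        rng = np.random.default_rng(seed)
        y = rng.random(80) < 0.5
        X = rng.poisson(0.5, (80, 12)).astype(float)
        X[:, 0] += 10 * y
        return X, y

    def test_subsample_full_population_matches(self):
        X, y = self._data()
        full = decode_binary(X, y, seed=17).accuracy
        curve = subsample_curve(X, y, [X.shape[1]], n_rep=1, seed=17)
        assert curve["accuracy"].iloc[0] == pytest.approx(full)

    def test_single_cell_decoding(self):
        X, y = self._data()
        res = single_cell_decode(X, y, n_shuffle=40, seed=18)
        assert res.loc[0, "accuracy"] == 1.0
        assert res.loc[0, "above_chance"]
        others = res.loc[1:, "accuracy"]
        assert (others - 0.5).abs().mean() < 0.15

    def test_subset_and_filter(self):
        X, y = self._data()
        feats = FeatureMatrix(X=X, meta=pd.DataFrame({"trial": np.arange(80)}))
        sub = subset_cells(feats, np.array([True] + [False] * 11))
        assert sub.X.shape == (80, 1)
        with pytest.raises(ValueError):
            subset_cells(feats, np.zeros(12, dtype=bool))
        filt = trial_filter(feats, (0, 27))
        assert filt.X.shape[0] == 27
        with pytest.raises(ValueError):
            trial_filter(feats, (100, 120))
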