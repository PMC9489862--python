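"""Movement controls: motion energy, bouts, triggered averages, regression."""

import numpy as np
import pytest

from barrelpop.movement import (behavior_features, build_event_regressor,
                                detect_bouts, event_triggered_average,
                                motion_energy, regress_events,
                                time_from_behavior)
from barrelpop.synth import calcium_kernel, generate_session
from tests.conftest import tiny_config


class TestMotionEnergy:
    def test_identical_frames_zero(self):
        frames = np.ones((10, 8, 8))
        roi = np.ones((8, 8), dtype=bool)
        assert np.allclose(motion_energy(frames, roi), 0.0)

    def test_alternating_frames(self):
        frames = np.zeros((6, 4, 4))
        frames[1::2] = 1.0
        trace = motion_energy(frames, np.ones((4, 4), dtype=bool))
        assert trace[0] == 0.0
        assert np.allclose(trace[1:], 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        frames = rng.random((20, 6, 6))
        roi = rng.random((6, 6)) < 0.5
        got = motion_energy(frames, roi)
        for t in range(1, 20):
            want = np.abs(frames[t][roi] - frames[t - 1][roi]).mean()
            assert got[t] == pytest.approx(want)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            motion_energy(np.zeros((5, 4, 4)), np.zeros((4, 4), dtype=bool))


class TestBouts:
    def _trace(self, pulse_times_s, rate=125.0, dur_s=20.0, seed=1):
        rng = np.random.default_rng(seed)
        n = int(dur_s * rate)
        trace = np.abs(rng.normal(0, 0.05, n))
        for t in pulse_times_s:
            i = int(t * rate)
            trace[i:i + 20] += 2.0
        return trace

    def test_flat_trace_no_bouts(self):
        with pytest.warns(UserWarning):
            assert detect_bouts(np.zeros(100), 125.0).size == 0

    def test_close_pulses_merge_into_one_bout(self):
        trace = self._trace([5.0, 5.3])
        onsets = detect_bouts(trace, 125.0, min_sep_s=0.5)
        assert len(onsets) == 1

    def test_separated_pulses_two_bouts(self):
        trace = self._trace([5.0, 6.0])
        onsets = detect_bouts(trace, 125.0, min_sep_s=0.5)
        assert len(onsets) == 2

    def test_min_separation_invariant(self):
        rng = np.random.default_rng(2)
        trace = np.abs(rng.normal(0, 1, 5000)) ** 3
        onsets = detect_bouts(trace, 125.0, min_sep_s=0.5)
        if len(onsets) > 1:
            assert np.diff(onsets).min() >= 0.5


class TestTriggeredAverage:
    def test_single_event_returns_segment(self):
        rng = np.random.default_rng(3)
        traces = rng.normal(0, 1, (2, 600))
        lags, per_cell, grand = event_triggered_average(
            traces, 30.0, [10.0], pre_s=1.0, post_s=2.0)
        f = 300
        assert np.allclose(per_cell, traces[:, f - 30:f + 60])

    def test_edge_events_excluded(self):
        traces = np.zeros((1, 300))
        with pytest.warns(UserWarning):
            lags, per_cell, _ = event_triggered_average(
                traces, 30.0, [0.1, 5.0], pre_s=1.0, post_s=2.0)
        with pytest.raises(ValueError):
            event_triggered_average(traces, 30.0, [0.1], pre_s=1.0, post_s=2.0)

    def test_locked_cell_peaks_at_lag_zero(self):
        rng = np.random.default_rng(4)
        fr = 30.0
        kernel = calcium_kernel(fr)
        events = np.array([20.0, 50.0, 80.0, 110.0, 140.0])
        n = int(170 * fr)
        sig = np.zeros(n)
        np.add.at(sig, (events * fr).astype(int), 5.0)
        trace = np.convolve(sig, kernel)[:n] + rng.normal(0, 0.3, n)
        lags, per_cell, grand = event_triggered_average(
            trace, fr, events, pre_s=1.0, post_s=2.0)
        peak_lag = lags[np.argmax(grand)]
        assert abs(peak_lag - kernel.argmax() / fr) <= 2 / fr


class TestRegression:
    def test_planted_coefficient_recovered_noiseless(self):
        fr = 30.0
        n = 3000
        onset_times = [10.0, 40.0, 70.0]
        reg = build_event_regressor(onset_times, n, fr)
        trace = 2.0 * reg
        out = regress_events(trace, fr,
                             event_regressors={"onset": onset_times,
                                               "reward": [20.0, 55.0]})
        assert out.loc[0, "onset"] == pytest.approx(2.0, abs=1e-6)
        assert out.loc[0, "reward"] == pytest.approx(0.0, abs=1e-6)
        assert out.loc[0, "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_trace_zero_coefficients(self):
        out = regress_events(np.zeros(1000), 30.0,
                             event_regressors={"onset": [5.0]})
        assert out.loc[0, "onset"] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            regress_events(np.zeros(500), 30.0,
                           event_regressors={"a": [3.0], "b": [3.0]})

    def test_whisk_driven_cell_recovered(self):
        rng = np.random.default_rng(5)
        n = 6000
        whisk = np.abs(rng.normal(0, 1, n))
        z = (whisk - whisk.mean()) / whisk.std()
        trace = 1.5 * z + rng.normal(0, 0.05, n)
        out = regress_events(trace, 30.0,
                             event_regressors={"onset": [10.0]},
                             continuous_regressors={"whisking": whisk})
        assert out.loc[0, "whisking"] == pytest.approx(1.5, rel=0.05)


class TestTimeFromBehavior:
    def test_deterministic_bin_function_identity(self, small_session):
        from barrelpop.session import AnalysisWindow
        sess, _ = small_session
        # motion trace that encodes trial phase exactly; with coarse bins
        # (4 intervals on a line) the decoder should be perfect
        fr, mr = sess.frame_rate, sess.motion_rate
        t = np.arange(int(sess.n_frames / fr * mr)) / mr
        starts = sess.trials["start_frame"].to_numpy() / fr
        phase = np.zeros_like(t)
        for s0 in starts:
            sel = (t >= s0 - 1.0) & (t < s0 + 5.0)
            phase[sel] = t[sel] - s0 + 2.0
        sess.motion_trace = phase
        res = time_from_behavior(sess, np.arange(len(sess.trials)),
                                 include=("whisking",), seed=1,
                                 window=AnalysisWindow(bin_frames=45))
        assert res.diagonal_accuracy > 0.95

    def test_uniform_whisking_near_chance(self, small_session):
        sess, _ = small_session
        rng = np.random.default_rng(6)
        sess.motion_trace = np.abs(rng.normal(0.5, 0.01,
                                              len(sess.motion_trace)))
        res = time_from_behavior(sess, np.arange(len(sess.trials)),
                                 include=("whisking",), seed=2)
        assert res.diagonal_accuracy < 0.3
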