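"""Fluorescence preprocessing: smoothing, dF/F, and transient detection.

The unit of analysis downstream is the *calcium transient*, not the raw
trace: each cell's fluorescence is Savitzky-Golay smoothed, converted to
dF/F against a slow rolling-percentile baseline (8th percentile of a 50 s
window centered on each frame), and thresholded at 2 standard deviations
above the cell's median dF/F. A transient starts at the first frame above
threshold and ends when the trace falls back below it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_filter


class DegenerateBaselineError(ValueError):
    pass


@dataclass
class TransientTrain:
    """Detected transients of one cell: half-open [onset, offset) frame intervals."""

    events: np.ndarray        # (k, 2) int64
    threshold: float

    @property
    def onsets(self) -> np.ndarray:
        return self.events[:, 0] if self.events.size else np.empty(0, dtype=np.int64)

    @property
    def n_events(self) -> int:
        return len(self.events)


def smooth_trace(trace, window_frames: int = 15, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay (local least-squares polynomial) smoothing."""
    trace = np.asarray(trace, dtype=float)
    if window_frames % 2 == 0 or window_frames <= polyorder:
        raise ValueError("window_frames must be odd and exceed polyorder")
    if trace.shape[-1] < window_frames:
        raise ValueError("trace shorter than smoothing window")
    return savgol_filter(trace, window_frames, polyorder, axis=-1)


def rolling_percentile(trace, window_frames: int, q: float) -> np.ndarray:
    """Exact centered rolling percentile, window truncated at the edges.

    The window at frame ``t`` is ``trace[t - half : t + half + 1]`` with
    ``half = window_frames // 2``, clipped to the trace. The interior is
    computed with an incrementally maintained sorted window (one value in,
    one out per frame), which is exact and much faster than re-sorting
    every window.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    half = window_frames // 2
    w = 2 * half + 1
    out = np.empty(n)
    lo = min(half, n)
    hi = max(n - half, lo)
    for t in range(lo):
        out[t] = np.percentile(trace[:min(t + half + 1, n)], q)
    for t in range(hi, n):
        out[t] = np.percentile(trace[max(0, t - half):], q)
    if hi > lo:
        buf = np.sort(trace[:w])
        qk = q / 100.0 * (w - 1)
        k, fr = int(qk), qk - int(qk)

        def pct(b):
            # same interpolation as np.percentile's default (linear)
            return b[k] + (b[min(k + 1, w - 1)] - b[k]) * fr

        out[lo] = pct(buf)
        for t in range(lo + 1, hi):
            old, new = trace[t - half - 1], trace[t + half]
            i = np.searchsorted(buf, old)
            j = np.searchsorted(buf, new)
            if j > i:
                buf[i:j - 1] = buf[i + 1:j]
                buf[j - 1] = new
            else:
                buf[j + 1:i + 1] = buf[j:i]
                buf[j] = new
            out[t] = pct(buf)
    return out


def compute_dff(raw, frame_rate: float, window_s: float = 50.0,
                percentile: float = 8.0) -> np.ndarray:
    """dF/F against a centered rolling-percentile baseline.

    ``dff(t) = (raw(t) - B(t)) / B(t)`` with ``B(t)`` the ``percentile``-th
    percentile of ``raw`` over a ``window_s`` window centered at ``t``
    (truncated at session edges). Raises if the baseline is non-positive
    anywhere, since the ratio is then meaningless.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 2:
        return np.vstack([compute_dff(r, frame_rate, window_s, percentile)
                          for r in raw])
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw trace contains non-finite values")
    window_frames = int(round(window_s * frame_rate))
    baseline = rolling_percentile(raw, window_frames, percentile)
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise DegenerateBaselineError(
            f"non-positive baseline at frame {int(bad[0])}")
    return (raw - baseline) / baseline


def detect_transients(dff, n_sd: float = 2.0) -> TransientTrain:
    """Threshold-crossing transient detection on one dF/F trace.

    Threshold = median + ``n_sd`` * SD of the full-session trace. An event
    begins at the first frame strictly above threshold and ends (exclusive)
    at the first frame at or below it.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.ndim != 1 or dff.shape[0] < 2:
        raise ValueError("dff must be a 1-D trace of length >= 2")
    sd = float(np.std(dff))
    if sd == 0.0:
        warnings.warn("zero-variance trace: no transients detectable")
        return TransientTrain(events=np.empty((0, 2), dtype=np.int64),
                              threshold=float(np.median(dff)))
    theta = float(np.median(dff)) + n_sd * sd
    above = dff > theta
    edges = np.diff(above.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    if above[-1]:
        offsets = np.concatenate([offsets, [dff.shape[0]]])
    events = np.stack([onsets, offsets], axis=1).astype(np.int64)
    return TransientTrain(events=events, threshold=theta)


def preprocess_session(session, smooth_window: int = 7, polyorder: int = 3,
                       dff_window_s: float = 50.0, dff_percentile: float = 8.0,
                       n_sd: float = 2.0):
    """Smooth -> dF/F -> transient trains for every cell of a session.

    Returns ``(dff, trains)`` with ``dff`` shaped like ``session.traces``.
    """
    smoothed = smooth_trace(session.traces, smooth_window, polyorder)
    dff = compute_dff(smoothed, session.frame_rate, dff_window_s,
                      dff_percentile)
    trains = [detect_transients(row, n_sd=n_sd) for row in dff]
    return dff, trains
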