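"""Movement controls: whisking motion energy, bouts, and event regression.

These analyses ask whether whisking or licking, rather than the stimulus
and its timing, can explain the neural effects: motion energy is the mean
absolute difference between consecutive whisker-video frames in a face
ROI; whisking bouts are threshold crossings of that trace (same
median + 2 SD rule as calcium transients) separated by at least 0.5 s;
whisk-triggered averages align fluorescence on bout onsets; a linear
regression decomposes each cell's trace into stimulus onset / offset /
reward / whisking / licking contributions; and the time decoder is re-run
on behavioral features alone.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .decode import FeatureMatrix, TimeDecodeResult, decode_time
from .session import AnalysisWindow, Session
from .synth import calcium_kernel


def motion_energy(frames: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Mean |frame(t) - frame(t-1)| over the ROI pixels; trace(0) = 0."""
    frames = np.asarray(frames, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if frames.shape[0] < 2:
        raise ValueError("need at least two video frames")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    diffs = np.abs(np.diff(frames[:, roi_mask], axis=0)).mean(axis=1)
    return np.concatenate([[0.0], diffs])


def detect_bouts(motion_trace: np.ndarray, rate_hz: float,
                 min_sep_s: float = 0.5, n_sd: float = 2.0) -> np.ndarray:
    """Whisking-bout onset times (s): threshold crossings >= min_sep apart."""
    trace = np.asarray(motion_trace, dtype=float)
    sd = trace.std()
    if sd == 0:
        warnings.warn("zero-variance motion trace: no bouts")
        return np.empty(0)
    theta = np.median(trace) + n_sd * sd
    above = trace > theta
    onsets = np.flatnonzero(np.diff(above.astype(np.int8)) == 1) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    times = onsets / rate_hz
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep_s:
            kept.append(float(t))
    return np.asarray(kept)


def event_triggered_average(traces: np.ndarray, frame_rate: float,
                            event_times: np.ndarray,
                            pre_s: float = 1.0, post_s: float = 2.0):
    """Mean trace segment aligned on event onsets, per cell and grand mean.

    Events whose window would leave the session are excluded (logged via
    warning); raises if no usable events remain. Returns
    ``(lags_s, per_cell_mean, grand_mean)``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_frames = traces.shape[1]
    pre = int(round(pre_s * frame_rate))
    post = int(round(post_s * frame_rate))
    segs = []
    n_skipped = 0
    for t in np.asarray(event_times, dtype=float):
        f = int(round(t * frame_rate))
        if f - pre < 0 or f + post > n_frames:
            n_skipped += 1
            continue
        segs.append(traces[:, f - pre:f + post])
    if n_skipped:
        warnings.warn(f"excluded {n_skipped} event(s) too close to session edges")
    if not segs:
        raise ValueError("no events fully inside the session")
    per_cell = np.mean(segs, axis=0)
    lags = (np.arange(-pre, post)) / frame_rate
    return lags, per_cell, per_cell.mean(axis=0)


def build_event_regressor(event_times, n_frames: int, frame_rate: float,
                          rise_tau_s: float = 0.05,
                          decay_tau_s: float = 0.4) -> np.ndarray:
    """Delta train at event times convolved with the calcium kernel."""
    delta = np.zeros(n_frames)
    frames = np.round(np.asarray(event_times, dtype=float) * frame_rate).astype(int)
    frames = frames[(frames >= 0) & (frames < n_frames)]
    np.add.at(delta, frames, 1.0)
    kernel = calcium_kernel(frame_rate, rise_tau_s, decay_tau_s)
    return np.convolve(delta, kernel)[:n_frames]


def regress_events(traces: np.ndarray, frame_rate: float,
                   event_regressors: Optional[dict] = None,
                   continuous_regressors: Optional[dict] = None) -> pd.DataFrame:
    """Per-cell ordinary least squares onto task and movement regressors.

    ``event_regressors`` maps name -> event times (s); each becomes a
    kernel-convolved delta train. ``continuous_regressors`` maps name ->
    trace on the imaging clock; each is z-scored. Returns one row per cell
    with the coefficients and R^2. Raises on a rank-deficient design,
    naming the collinear columns.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_frames = traces.shape[1]
    names, cols = [], []
    for name, times in (event_regressors or {}).items():
        names.append(name)
        cols.append(build_event_regressor(times, n_frames, frame_rate))
    for name, tr in (continuous_regressors or {}).items():
        tr = np.asarray(tr, dtype=float)
        sd = tr.std()
        names.append(name)
        cols.append((tr - tr.mean()) / sd if sd > 0 else tr - tr.mean())
    if not names:
        raise ValueError("no regressors given")
    design = np.column_stack(cols + [np.ones(n_frames)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank
        bad = []
        for k in range(design.shape[1] - 1):
            others = np.delete(design, k, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[k])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    coefs, _, _, _ = np.linalg.lstsq(design, traces.T, rcond=None)
    fitted = design @ coefs
    resid = traces.T - fitted
    ss_res = (resid ** 2).sum(axis=0)
    centered = traces.T - traces.T.mean(axis=0)
    ss_tot = (centered ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    out = pd.DataFrame(coefs[:-1].T, columns=names)
    out["intercept"] = coefs[-1]
    out["r2"] = r2
    return out


def behavior_features(session: Session, window: Optional[AnalysisWindow] = None,
                      include=("whisking", "licking", "events")) -> FeatureMatrix:
    """Per-(trial, bin) behavioral features for time decoding.

    Whisking: mean motion energy per imaging time bin (video trace
    interpolated onto the imaging clock); licking: lick count per bin;
    events: indicator of stimulus onset / offset / reward falling in the bin.
    """
    if window is None:
        window = AnalysisWindow()
    fr = session.frame_rate
    bf = window.bin_frames
    n_win = window.n_frames(fr)
    n_bins = n_win // bf
    pre = window.pre_frames(fr)
    mask = session.valid_trial_mask(window)
    trials = session.trials[mask]
    trial_ids = np.flatnonzero(mask)
    whisk_img = None
    if "whisking" in include and session.motion_trace is not None:
        t_img = np.arange(session.n_frames) / fr
        t_vid = np.arange(len(session.motion_trace)) / session.motion_rate
        whisk_img = np.interp(t_img, t_vid, session.motion_trace)
    cols = []
    if whisk_img is not None:
        cols.append("whisking")
    if "licking" in include:
        cols.append("licking")
    if "events" in include:
        cols += ["ev_onset", "ev_offset", "ev_reward"]
    rows_X, rows_meta = [], []
    for row_i, trial in enumerate(trials.itertuples()):
        sf = int(trial.start_frame)
        t0 = sf / fr
        for b in range(n_bins):
            f_lo = sf - pre + b * bf
            t_lo, t_hi = f_lo / fr - t0, (f_lo + bf) / fr - t0
            feats = []
            if whisk_img is not None:
                feats.append(float(whisk_img[f_lo:f_lo + bf].mean()))
            if "licking" in include:
                rel = session.lick_times - t0
                feats.append(float(np.sum((rel >= t_lo) & (rel < t_hi))))
            if "events" in include:
                feats.append(float(t_lo <= 0.0 < t_hi and trial.stimulus_present))
                feats.append(float(t_lo <= trial.depart_t < t_hi
                                   and trial.stimulus_present))
                rew = trial.reward_t
                feats.append(float(not np.isnan(rew) and t_lo <= rew < t_hi))
            rows_X.append(feats)
            rows_meta.append(dict(trial=int(trial_ids[row_i]), bin=b,
                                  time_s=(t_lo + t_hi) / 2))
    return FeatureMatrix(X=np.asarray(rows_X),
                         meta=pd.DataFrame(rows_meta))


def time_from_behavior(session: Session, train_trials, test_trials=None,
                       window: Optional[AnalysisWindow] = None,
                       include=("whisking", "licking", "events"),
                       folds: int = 4, seed: int = 0) -> TimeDecodeResult:
    """Decode time-bin identity from behavioral features alone."""
    feats = behavior_features(session, window=window, include=include)
    return decode_time(feats, train_trials, test_trials, folds=folds,
                       seed=seed)
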