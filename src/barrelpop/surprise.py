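"""Temporal-surprise (delayed-offset) analysis.

In expert mice the stimulus offset is delayed by 1 s on a random 20% of
trials. Because the stimulus itself is unchanged, any extra response to
the delayed offset reflects a violated temporal expectation. Per cell we
compare the late-peak dF/F amplitude (max in a 1-s window from each
trial's *actual* departure, minus a 0.5-s pre-departure baseline) between
normal and delayed trials with a two-sided rank-sum test, FDR-corrected
across cells; at the population level, a Wilcoxon signed-rank test on the
per-cell mean pairs. The same machinery compares onset vs offset
responses within a condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import ranksums, wilcoxon
from statsmodels.stats.multitest import multipletests

from .session import DEPART_T, DEPART_T_DELAYED, AnalysisWindow, Session


def trial_aligned_dff(dff: np.ndarray, session: Session,
                      window: AnalysisWindow):
    """(cells x trials x window-frames) dF/F segments + kept-trial indices."""
    mask = session.valid_trial_mask(window)
    starts = session.trials["start_frame"].to_numpy()[mask]
    fr = session.frame_rate
    n_win = window.n_frames(fr)
    pre = window.pre_frames(fr)
    segs = np.empty((dff.shape[0], len(starts), n_win))
    for i, sf in enumerate(starts):
        segs[:, i, :] = dff[:, int(sf) - pre:int(sf) - pre + n_win]
    return segs, np.flatnonzero(mask)


def window_amplitude(aligned: np.ndarray, frame_times: np.ndarray,
                     window: tuple, baseline_s: float = 0.5) -> np.ndarray:
    """Per-trial amplitude: max dF/F in ``window`` minus pre-window baseline.

    ``aligned`` is (trials x frames) for one cell (or cells x trials x
    frames); ``window = (a, b)`` in trial-relative seconds; baseline is the
    mean over ``[a - baseline_s, a)``.
    """
    a, b = window
    in_win = (frame_times >= a) & (frame_times < b)
    in_base = (frame_times >= a - baseline_s) & (frame_times < a)
    if not in_win.any() or not in_base.any():
        raise ValueError("amplitude window outside the trial segment")
    arr = np.asarray(aligned)
    return arr[..., in_win].max(axis=-1) - arr[..., in_base].mean(axis=-1)


def offset_amplitudes(dff: np.ndarray, session: Session,
                      window: Optional[AnalysisWindow] = None,
                      stimulus_only: bool = True):
    """Late-peak amplitudes on normal vs delayed trials, per cell.

    The offset window is ``[depart_t, depart_t + 1)`` using each trial's
    own departure time. Returns ``(amp_normal, amp_delayed)``, each
    (cells x trials-of-that-condition).
    """
    if window is None:
        window = AnalysisWindow(pre_s=1.0, post_s=6.0)
    segs, kept = trial_aligned_dff(dff, session, window)
    times = window.frame_times(session.frame_rate)
    trials = session.trials.iloc[kept]
    delayed = trials["delayed_offset"].to_numpy(dtype=bool)
    stim = trials["stimulus_present"].to_numpy(dtype=bool)
    sel_n = ~delayed & (stim if stimulus_only else True)
    sel_d = delayed & (stim if stimulus_only else True)
    amp_n = window_amplitude(segs[:, sel_n, :], times,
                             (DEPART_T, DEPART_T + 1.0))
    amp_d = window_amplitude(segs[:, sel_d, :], times,
                             (DEPART_T_DELAYED, DEPART_T_DELAYED + 1.0))
    return amp_n, amp_d


def onset_amplitudes(dff: np.ndarray, session: Session,
                     window: Optional[AnalysisWindow] = None,
                     delayed: bool = False):
    """Stimulus-onset amplitudes ([0, 1) s window) on one trial condition."""
    if window is None:
        window = AnalysisWindow(pre_s=1.0, post_s=6.0)
    segs, kept = trial_aligned_dff(dff, session, window)
    times = window.frame_times(session.frame_rate)
    trials = session.trials.iloc[kept]
    sel = (trials["stimulus_present"].to_numpy(dtype=bool)
           & (trials["delayed_offset"].to_numpy(dtype=bool) == delayed))
    return window_amplitude(segs[:, sel, :], times, (0.0, 1.0))


@dataclass
class SurpriseResult:
    per_cell: pd.DataFrame       # mean_a, mean_b, p, significant, rel_change
    fraction_significant: float
    mean_rel_change: float       # over significant cells
    population_p: float          # Wilcoxon signed-rank on per-cell means
    alpha: float


def compare_conditions(amplitudes_a: np.ndarray, amplitudes_b: np.ndarray,
                       alpha: float = 0.05) -> SurpriseResult:
    """Per-cell and population comparison of two amplitude conditions.

    ``amplitudes_x`` are (cells x trials) matrices of trial-wise
    amplitudes (trial counts may differ between conditions). A is the
    reference (e.g. normal offset), B the comparison (delayed offset);
    relative change is (mean_B - mean_A) / mean_A.
    """
    A = np.atleast_2d(np.asarray(amplitudes_a, dtype=float))
    B = np.atleast_2d(np.asarray(amplitudes_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("conditions must cover the same cells")
    if A.shape[1] < 5 or B.shape[1] < 5:
        raise ValueError("need >= 5 trials per condition")
    rows = []
    for c in range(A.shape[0]):
        a, b = A[c], B[c]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p = 1.0
        else:
            p = float(ranksums(a, b).pvalue)
        ma, mb = float(a.mean()), float(b.mean())
        rows.append(dict(mean_a=ma, mean_b=mb, p=p,
                         rel_change=(mb - ma) / ma if ma != 0 else np.nan))
    per_cell = pd.DataFrame(rows)
    per_cell["significant"] = multipletests(per_cell["p"], alpha=alpha,
                                            method="fdr_bh")[0]
    sig = per_cell["significant"].to_numpy()
    diffs = per_cell["mean_b"] - per_cell["mean_a"]
    pop_p = float(wilcoxon(per_cell["mean_a"], per_cell["mean_b"]).pvalue) \
        if np.any(diffs != 0) else 1.0
    mean_rel = float(per_cell.loc[sig, "rel_change"].mean()) if sig.any() \
        else float("nan")
    return SurpriseResult(per_cell=per_cell,
                          fraction_significant=float(sig.mean()),
                          mean_rel_change=mean_rel,
                          population_p=pop_p, alpha=alpha)


def offset_peak_latency_shift(dff: np.ndarray, session: Session,
                              cells, window: Optional[AnalysisWindow] = None,
                              search: tuple = (1.5, 5.9)) -> pd.DataFrame:
    """Peak latency of the trial-averaged response, normal vs delayed.

    For the given cells (typically "off" cells), the trial-averaged dF/F
    is searched for its peak in a common window; the latency difference
    (delayed - normal) shows whether the response re-locks to the shifted
    offset (a shift of ~1 s).
    """
    if window is None:
        window = AnalysisWindow(pre_s=1.0, post_s=6.0)
    segs, kept = trial_aligned_dff(dff, session, window)
    times = window.frame_times(session.frame_rate)
    trials = session.trials.iloc[kept]
    stim = trials["stimulus_present"].to_numpy(dtype=bool)
    delayed = trials["delayed_offset"].to_numpy(dtype=bool)
    in_search = (times >= search[0]) & (times < search[1])
    rows = []
    for c in cells:
        avg_n = segs[c][stim & ~delayed].mean(axis=0)
        avg_d = segs[c][stim & delayed].mean(axis=0)
        t_n = float(times[in_search][np.argmax(avg_n[in_search])])
        t_d = float(times[in_search][np.argmax(avg_d[in_search])])
        rows.append(dict(cell=int(c), peak_normal_s=t_n, peak_delayed_s=t_d,
                         shift_s=t_d - t_n))
    return pd.DataFrame(rows)


def surprise_summary(classifications, result: SurpriseResult,
                     dff: Optional[np.ndarray] = None,
                     session: Optional[Session] = None,
                     window: Optional[AnalysisWindow] = None) -> dict:
    """Category composition of surprise cells, plus off-cell latency shifts."""
    labels = np.asarray([c.label if hasattr(c, "label") else c
                         for c in classifications])
    sig = result.per_cell["significant"].to_numpy()
    comp = {}
    for lab in np.unique(labels[sig]) if sig.any() else []:
        comp[str(lab)] = int(np.sum(sig & (labels == lab)))
    out = {"composition": comp,
           "n_significant": int(sig.sum()),
           "fraction_significant": result.fraction_significant}
    if dff is not None and session is not None:
        off_cells = np.flatnonzero(labels == "off")
        if off_cells.size:
            shifts = offset_peak_latency_shift(dff, session, off_cells,
                                               window=window)
            out["off_cell_latency_shift"] = shifts
            out["median_off_shift_s"] = float(shifts["shift_s"].median())
    return out
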