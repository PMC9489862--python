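"""Trial outcome labeling, session performance, and lick histograms.

The task is Pavlovian, so "choice" is read out purely from anticipatory
licking: at least one lick in the anticipatory window (the 2 s while the
object is stationary, [0.5 s, depart) trial-relative) counts as a lick
response. Crossing that with stimulus presence yields the four standard
outcomes (hit / miss / false alarm / correct rejection), and performance is
(hits + correct rejections) / trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .session import STOP_T, Session


def anticipatory_lick_counts(session: Session,
                             window_start: float = STOP_T) -> np.ndarray:
    """Licks per trial in the anticipatory window [window_start, depart_t)."""
    counts = np.zeros(len(session.trials), dtype=int)
    licks = session.lick_times
    fr = session.frame_rate
    for trial in session.trials.itertuples():
        t0 = trial.start_frame / fr
        a, b = t0 + window_start, t0 + trial.depart_t
        counts[trial.Index] = int(np.sum((licks >= a) & (licks < b)))
    return counts


def label_trials(session: Session) -> pd.DataFrame:
    """Return a copy of the trial table with ``response_label`` filled."""
    counts = anticipatory_lick_counts(session)
    licked = counts >= 1
    stim = session.trials["stimulus_present"].to_numpy(dtype=bool)
    labels = np.where(stim,
                      np.where(licked, "hit", "miss"),
                      np.where(licked, "false_alarm", "correct_rejection"))
    out = session.trials.copy()
    out["response_label"] = labels
    return out


def session_performance(labels: pd.DataFrame) -> float:
    if len(labels) == 0:
        raise ValueError("cannot compute performance of an empty trial table")
    lab = labels["response_label"]
    correct = lab.isin(["hit", "correct_rejection"]).sum()
    return float(correct / len(labels))


def lick_rate_histogram(session: Session, trial_index, bin_s: float = 0.1,
                        pre_s: float = 1.0, post_s: float = 5.0):
    """Pooled lick rate (licks/s) per trial-relative time bin.

    Counts are pooled over the selected trials and divided by
    ``n_trials * bin_s``. Returns ``(bin_edges, rates)``.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    trial_index = np.asarray(trial_index)
    if trial_index.dtype == bool:
        trial_index = np.flatnonzero(trial_index)
    if trial_index.size == 0:
        raise ValueError("empty trial subset")
    edges = np.arange(-pre_s, post_s + bin_s / 2, bin_s)
    counts = np.zeros(len(edges) - 1)
    fr = session.frame_rate
    for i in trial_index:
        t0 = session.trials["start_frame"].iloc[int(i)] / fr
        rel = session.lick_times - t0
        counts += np.histogram(rel, bins=edges)[0]
    return edges, counts / (trial_index.size * bin_s)
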