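"""Shuffle-based classification of cells into response categories.

Each cell's trial-aligned transient-onset raster is summarized as a
probability curve (fraction of trials with an onset at each trial-time
frame). A circular-shuffle null -- every trial's events rotated by an
independent uniform offset within the trial window, preserving per-trial
counts and autocorrelation -- gives the chance distribution of that curve.
The mean probability in three 1-s windows (stimulus onset [0, 1) s, offset
[2.5, 3.5) s, and post-reward [3.5, 4.5) s) is compared to the null by a
one-sided z-test (excess only), Benjamini-Hochberg corrected across all
cells x windows, and the pattern of significant windows determines the
label:

* onset and offset significant -> "on-off"
* reward significant, onset not -> "reward"
* onset only -> "on"; offset only -> "off"; nothing -> "none"

The reward window is placed after the offset window so the two are
disjoint and the labels well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .session import AnalysisWindow, Session

#: trial-relative 1-s windows (seconds) used for classification
DEFAULT_WINDOWS = {"onset": (0.0, 1.0), "offset": (2.5, 3.5),
                   "reward": (3.5, 4.5)}


def build_raster(train, session: Session, window: AnalysisWindow,
                 trial_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Binary (trials x window-frames) onset raster for one cell."""
    fr = session.frame_rate
    n_win = window.n_frames(fr)
    if trial_mask is None:
        trial_mask = session.valid_trial_mask(window)
    starts = session.trials["start_frame"].to_numpy()[trial_mask]
    raster = np.zeros((len(starts), n_win), dtype=np.uint8)
    onsets = train.onsets
    pre = window.pre_frames(fr)
    for i, sf in enumerate(starts):
        rel = onsets - (int(sf) - pre)
        rel = rel[(rel >= 0) & (rel < n_win)]
        raster[i, rel] = 1
    return raster


def build_rasters(trains, session: Session, window: AnalysisWindow,
                  trial_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """(cells x trials x window-frames) onset rasters."""
    if trial_mask is None:
        trial_mask = session.valid_trial_mask(window)
    return np.stack([build_raster(t, session, window, trial_mask)
                     for t in trains])


def transient_probability(raster: np.ndarray) -> np.ndarray:
    """P(onset at each trial-time frame) = column mean of the raster."""
    raster = np.asarray(raster)
    if raster.ndim != 2 or raster.shape[0] == 0:
        raise ValueError("raster must be a non-empty (trials x frames) matrix")
    return raster.mean(axis=0)


def circular_shuffle_null(raster: np.ndarray, n_iter: int = 5000,
                          seed: int = 0,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Null probability curves from per-trial circular rotation.

    Each iteration independently rotates every trial's row by a uniform
    random offset (wrap-around within the trial window) and recomputes the
    probability curve; per-trial event counts are conserved exactly.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    raster = np.asarray(raster)
    n_trials, n_frames = raster.shape
    if rng is None:
        rng = np.random.default_rng(seed)
    trial_idx, frame_idx = np.nonzero(raster)
    offsets = rng.integers(0, n_frames, size=(n_iter, n_trials))
    if trial_idx.size == 0:
        return np.zeros((n_iter, n_frames))
    shifted = (frame_idx[None, :] + offsets[:, trial_idx]) % n_frames
    flat = (np.arange(n_iter)[:, None] * n_frames + shifted).ravel()
    counts = np.bincount(flat, minlength=n_iter * n_frames)
    return counts.reshape(n_iter, n_frames) / n_trials


def window_frame_slices(window: AnalysisWindow, frame_rate: float,
                        windows=None) -> dict:
    """Frame slices (into the trial window) of the classification windows."""
    if windows is None:
        windows = DEFAULT_WINDOWS
    pre = window.pre_frames(frame_rate)
    out = {}
    for name, (a, b) in windows.items():
        out[name] = slice(pre + int(round(a * frame_rate)),
                          pre + int(round(b * frame_rate)))
    return out


@dataclass
class CellClassification:
    label: str
    stats: pd.DataFrame     # per window: obs, null_mean, null_sd, z, p, significant
    n_shuffles: int


def _window_stats(prob_curve, null_curves, slices) -> pd.DataFrame:
    rows = {}
    for name, sl in slices.items():
        obs = float(prob_curve[sl].mean())
        null = null_curves[:, sl].mean(axis=1)
        mu, sd = float(null.mean()), float(null.std())
        if sd > 0:
            z = (obs - mu) / sd
            p = float(norm.sf(z))
        elif obs > mu:
            z, p = np.inf, 0.0          # excess over an exactly-constant null
        else:
            z, p = 0.0, 1.0
        rows[name] = dict(obs=obs, null_mean=mu, null_sd=sd, z=z, p=p)
    return pd.DataFrame(rows).T


def label_from_flags(onset: bool, offset: bool, reward: bool) -> str:
    if onset and offset:
        return "on_off"
    if reward and not onset:
        return "reward"
    if onset:
        return "on"
    if offset:
        return "off"
    return "none"


def classify_cell(prob_curve, null_curves, slices, alpha: float = 0.05,
                  adjusted_significant=None) -> CellClassification:
    """Classify one cell; ``adjusted_significant`` (per window) overrides the
    raw-alpha decision when an FDR correction has been applied across cells."""
    stats = _window_stats(prob_curve, null_curves, slices)
    if adjusted_significant is None:
        stats["significant"] = stats["p"] < alpha
    else:
        stats["significant"] = [bool(adjusted_significant[name])
                                for name in stats.index]
    label = label_from_flags(*[bool(stats.loc[k, "significant"])
                               for k in ("onset", "offset", "reward")])
    return CellClassification(label=label, stats=stats,
                              n_shuffles=null_curves.shape[0])


def classify_cells(trains, session: Session,
                   window: Optional[AnalysisWindow] = None,
                   windows=None, n_iter: int = 5000, alpha: float = 0.05,
                   seed: int = 0, trial_subset="stimulus") -> list:
    """Classify every cell of a session with BH-FDR across cells x windows.

    ``trial_subset`` selects the trials the rasters are built from:
    ``"stimulus"`` (default) uses stimulus-present trials, since the
    events that define the categories (object arrival, departure, reward)
    only occur there; ``"all"`` uses every trial; a boolean mask selects
    arbitrary trials.
    """
    if window is None:
        window = AnalysisWindow()
    slices = window_frame_slices(window, session.frame_rate, windows)
    names = list(slices)
    trial_mask = session.valid_trial_mask(window)
    if isinstance(trial_subset, str):
        if trial_subset == "stimulus":
            trial_mask &= session.trials["stimulus_present"].to_numpy(dtype=bool)
        elif trial_subset != "all":
            raise ValueError(f"unknown trial_subset {trial_subset!r}")
    else:
        trial_mask &= np.asarray(trial_subset, dtype=bool)
    rng = np.random.default_rng(seed)
    all_stats = []
    for train in trains:
        raster = build_raster(train, session, window, trial_mask)
        curve = transient_probability(raster)
        nulls = circular_shuffle_null(raster, n_iter=n_iter, rng=rng)
        all_stats.append(_window_stats(curve, nulls, slices))
    pvals = np.array([[s.loc[n, "p"] for n in names] for s in all_stats])
    reject = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")[0] \
        .reshape(pvals.shape)
    out = []
    for stats, rej in zip(all_stats, reject):
        stats = stats.copy()
        stats["significant"] = rej
        label = label_from_flags(*[bool(stats.loc[k, "significant"])
                                   for k in ("onset", "offset", "reward")])
        out.append(CellClassification(label=label, stats=stats,
                                      n_shuffles=n_iter))
    return out


def category_counts(classifications) -> dict:
    from .synth import CELL_TYPES
    labels = [c.label if hasattr(c, "label") else c for c in classifications]
    return {t: int(sum(l == t for l in labels)) for t in CELL_TYPES}


def proportion_change_test(counts_A: dict, n_A: int, counts_B: dict,
                           n_B: int) -> pd.DataFrame:
    """Two-proportion z-test per category, Bonferroni-corrected.

    Compares category proportions between two cell populations (e.g. naive
    vs expert days) with the pooled-variance normal approximation to the
    binomial; two-sided p-values are multiplied by the number of
    categories.
    """
    if n_A < 1 or n_B < 1:
        raise ValueError("population sizes must be >= 1")
    cats = sorted(set(counts_A) | set(counts_B))
    rows = []
    for cat in cats:
        a, b = counts_A.get(cat, 0), counts_B.get(cat, 0)
        if a > n_A or b > n_B:
            raise ValueError(f"count exceeds population size for {cat!r}")
        p1, p2 = a / n_A, b / n_B
        pool = (a + b) / (n_A + n_B)
        if pool in (0.0, 1.0):
            warnings.warn(f"category {cat!r}: pooled proportion degenerate")
            rows.append(dict(category=cat, z=0.0, p=1.0, p_corrected=1.0,
                             direction="none"))
            continue
        se = np.sqrt(pool * (1 - pool) * (1 / n_A + 1 / n_B))
        z = (p2 - p1) / se
        p = 2 * norm.sf(abs(z))
        rows.append(dict(category=cat, z=float(z), p=float(p),
                         p_corrected=float(min(1.0, p * len(cats))),
                         direction="increase" if z > 0 else
                         ("decrease" if z < 0 else "none")))
    return pd.DataFrame(rows).set_index("category")
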