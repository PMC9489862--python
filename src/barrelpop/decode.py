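"""Cross-validated linear decoding of stimulus, choice, and trial time.

Features are per-trial (or per time-bin) counts of calcium-transient
onsets per cell. Binary targets (stimulus present/absent, lick/no-lick)
are decoded with a linear maximum-margin classifier (SVM) under 4-fold
cross-validation, with class balancing by subsampling (default) or by
inverse-frequency sample weights over the stimulus x choice cells
(trial balancing). Class separability is quantified as the 1-D earth
mover's distance between the two classes' projections on the unit coding
axis. Time decoding treats the bin index as a multi-class target (joint
multi-class linear SVM) and reports a row-normalized confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.exceptions import ConvergenceWarning
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .session import AnalysisWindow, Session

warnings.filterwarnings("ignore", category=ConvergenceWarning)


@dataclass
class FeatureMatrix:
    """Samples x cells transient counts plus per-sample metadata."""

    X: np.ndarray
    meta: pd.DataFrame      # columns: trial, and for time bins: bin, time_s

    def __post_init__(self):
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata length must equal sample count")


def build_features(trains, session: Session, mode: str = "trial_window",
                   feature_window: tuple = (0.0, 4.0),
                   window: Optional[AnalysisWindow] = None) -> FeatureMatrix:
    """Transient-onset count features.

    ``trial_window`` mode: one sample per trial, counting onsets in the
    trial-relative ``feature_window`` (seconds). ``time_bins`` mode: one
    sample per (trial, bin) with bins of ``window.bin_frames`` frames over
    the analysis window, trailing partial bin truncated.
    """
    if window is None:
        window = AnalysisWindow()
    fr = session.frame_rate
    mask = session.valid_trial_mask(window)
    trials = session.trials[mask]
    starts = trials["start_frame"].to_numpy()
    trial_ids = np.flatnonzero(mask)
    if mode == "trial_window":
        a, b = feature_window
        fa, fb = int(round(a * fr)), int(round(b * fr))
        if fb <= fa:
            raise ValueError("empty feature window")
        X = np.zeros((len(starts), len(trains)), dtype=int)
        for c, train in enumerate(trains):
            on = train.onsets
            for i, sf in enumerate(starts):
                X[i, c] = int(np.sum((on >= sf + fa) & (on < sf + fb)))
        meta = pd.DataFrame({"trial": trial_ids})
        return FeatureMatrix(X=X, meta=meta)
    if mode == "time_bins":
        n_win = window.n_frames(fr)
        bf = window.bin_frames
        n_bins = n_win // bf
        pre = window.pre_frames(fr)
        X = np.zeros((len(starts) * n_bins, len(trains)), dtype=int)
        for c, train in enumerate(trains):
            on = train.onsets
            for i, sf in enumerate(starts):
                rel = on - (int(sf) - pre)
                rel = rel[(rel >= 0) & (rel < n_bins * bf)]
                if rel.size:
                    counts = np.bincount(rel // bf, minlength=n_bins)
                    X[i * n_bins:(i + 1) * n_bins, c] = counts
        t_mid = (np.arange(n_bins) * bf + bf / 2 - pre) / fr
        meta = pd.DataFrame({
            "trial": np.repeat(trial_ids, n_bins),
            "bin": np.tile(np.arange(n_bins), len(starts)),
            "time_s": np.tile(t_mid, len(starts)),
        })
        return FeatureMatrix(X=X, meta=meta)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DecodeResult:
    accuracy: float
    fold_accuracies: np.ndarray
    weights: np.ndarray              # mean over folds, standardized space
    projections: np.ndarray          # all samples on the unit coding axis
    labels: np.ndarray
    balance: str
    null_accuracies: Optional[np.ndarray] = None

    @property
    def null_mean(self):
        return None if self.null_accuracies is None else float(
            self.null_accuracies.mean())

    @property
    def null_interval_99(self):
        if self.null_accuracies is None:
            return None
        return tuple(np.percentile(self.null_accuracies, [0.5, 99.5]))

    @property
    def separability(self) -> float:
        return separability(self.projections, self.labels)


def _fit_svm(Xtr, ytr, C, sample_weight=None, multiclass=False):
    scaler = StandardScaler().fit(Xtr)
    if multiclass:
        # multi-class linear SVM (Crammer-Singer joint formulation)
        clf = LinearSVC(C=C, max_iter=5000, multi_class="crammer_singer")
        clf.fit(scaler.transform(Xtr), ytr)
    else:
        clf = LinearSVC(C=C, dual="auto", max_iter=5000)
        clf.fit(scaler.transform(Xtr), ytr, sample_weight=sample_weight)
    return scaler, clf


def _stratified_folds(y, folds, rng):
    """Deterministic stratified fold assignment per sample."""
    assign = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def _cv_accuracy(X, y, folds, C, rng, sample_weight=None):
    assign = _stratified_folds(y, folds, rng)
    accs, ws = [], []
    for k in range(folds):
        tr, te = assign != k, assign == k
        sw = sample_weight[tr] if sample_weight is not None else None
        scaler, clf = _fit_svm(X[tr], y[tr], C, sw)
        accs.append(float(np.mean(clf.predict(scaler.transform(X[te])) == y[te])))
        ws.append(clf.coef_.ravel())
    return np.asarray(accs), np.mean(ws, axis=0)


def decode_binary(X, y, folds: int = 4, balance: str = "subsample",
                  n_shuffle: int = 0, seed: int = 0, C: float = 1.0,
                  weight_groups=None) -> DecodeResult:
    """Cross-validated linear-SVM decoding of a binary label.

    ``balance='subsample'`` randomly equalizes class counts before folding
    (the trial-matching approach); ``balance='weight'`` keeps all samples
    but weights each inversely to the frequency of its ``weight_groups``
    cell (trial balancing over stimulus x choice); ``balance='none'``
    uses samples as-is. ``n_shuffle`` > 0 adds a label-permutation null.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("decode_binary requires exactly two classes")
    rng = np.random.default_rng(seed)
    if balance == "subsample":
        n_min = min(int(np.sum(y == c)) for c in classes)
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
            for c in classes])
        keep.sort()
        X, y = X[keep], y[keep]
        sample_weight = None
    elif balance == "weight":
        groups = np.asarray(weight_groups if weight_groups is not None else y)
        freq = pd.Series(groups).value_counts(normalize=True)
        sample_weight = np.array([1.0 / freq[g] for g in groups])
    elif balance == "none":
        sample_weight = None
    else:
        raise ValueError(f"unknown balance mode {balance!r}")
    counts = [int(np.sum(y == c)) for c in classes]
    if min(counts) < folds:
        raise ValueError(f"class count {min(counts)} < folds={folds}")
    accs, w = _cv_accuracy(X, y, folds, C, rng, sample_weight)
    # projections on the unit coding axis of standardized features
    scaler, clf = _fit_svm(X, y, C, sample_weight)
    axis = clf.coef_.ravel()
    axis = axis / np.linalg.norm(axis)
    proj = scaler.transform(X) @ axis
    null = None
    if n_shuffle > 0:
        null = np.empty(n_shuffle)
        for s in range(n_shuffle):
            ys = rng.permutation(y)
            null[s] = _cv_accuracy(X, ys, folds, C, rng, sample_weight)[0].mean()
    return DecodeResult(accuracy=float(accs.mean()), fold_accuracies=accs,
                        weights=w, projections=proj, labels=y,
                        balance=balance, null_accuracies=null)


def separability(projections, labels) -> float:
    """Earth mover's distance between the two classes' 1-D projections."""
    projections = np.asarray(projections, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("separability requires exactly two classes")
    a = projections[labels == classes[0]]
    b = projections[labels == classes[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty class")
    return float(wasserstein_distance(a, b))


@dataclass
class TimecourseResult:
    bin_accuracy: np.ndarray
    null_99: np.ndarray               # per-bin 99th percentile of shuffles
    significant: np.ndarray           # bool per bin
    first_significant_bin: Optional[int]
    time_s: np.ndarray


def decode_timecourse(features: FeatureMatrix, trial_labels: dict,
                      folds: int = 4, n_shuffle: int = 100, seed: int = 0,
                      C: float = 1.0, balance: str = "subsample",
                      require_consecutive: int = 1) -> TimecourseResult:
    """Per-time-bin decoding of a binary trial label.

    ``trial_labels`` maps trial index -> label. Each bin is decoded
    independently from that bin's counts; a bin is significant when the
    real accuracy exceeds the 99th percentile of its label-shuffle null.
    The first significant bin is the earliest run of
    ``require_consecutive`` significant bins.
    """
    bins = np.sort(features.meta["bin"].unique())
    acc = np.empty(len(bins))
    null99 = np.full(len(bins), np.nan)
    time_s = np.empty(len(bins))
    rng = np.random.default_rng(seed)
    for bi, b in enumerate(bins):
        sel = features.meta["bin"].to_numpy() == b
        Xb = features.X[sel]
        yb = np.array([trial_labels[t] for t in
                       features.meta.loc[sel, "trial"]])
        res = decode_binary(Xb, yb, folds=folds, balance=balance,
                            n_shuffle=n_shuffle,
                            seed=int(rng.integers(2 ** 31)), C=C)
        acc[bi] = res.accuracy
        if n_shuffle > 0:
            null99[bi] = float(np.percentile(res.null_accuracies, 99))
        time_s[bi] = features.meta.loc[sel, "time_s"].iloc[0]
    significant = acc > null99
    first = None
    k = require_consecutive
    for i in range(len(bins) - k + 1):
        if significant[i:i + k].all():
            first = int(bins[i])
            break
    return TimecourseResult(bin_accuracy=acc, null_99=null99,
                            significant=significant,
                            first_significant_bin=first, time_s=time_s)


@dataclass
class TimeDecodeResult:
    confusion: np.ndarray        # rows = true bin, row-normalized; NaN if absent
    row_support: np.ndarray      # test samples per true bin
    bin_frames: int
    train_condition: str
    test_condition: str

    @property
    def diagonal_accuracy(self) -> float:
        d = np.diag(self.confusion)
        return float(np.nanmean(d))

    @property
    def mean_abs_error_bins(self) -> float:
        n = self.confusion.shape[0]
        errs, weights = [], []
        for r in range(n):
            if self.row_support[r] > 0:
                errs.append(np.nansum(self.confusion[r] *
                                      np.abs(np.arange(n) - r)))
                weights.append(self.row_support[r])
        return float(np.average(errs, weights=weights))


def decode_time(features: FeatureMatrix, train_trials, test_trials=None,
                folds: int = 4, seed: int = 0, C: float = 1.0,
                bin_frames: int = 10, train_condition: str = "train",
                test_condition: str = "test") -> TimeDecodeResult:
    """Multi-class linear-SVM decoding of time-bin identity.

    Same-condition evaluation (``test_trials`` None or equal to
    ``train_trials``) uses ``folds``-fold cross-validation over *trials*;
    cross-condition evaluation trains on all train-condition trials and
    tests on all test-condition trials. The confusion matrix is
    row-normalized over true bins; rows with no test samples are NaN.
    """
    train_trials = np.asarray(sorted(set(train_trials)))
    if train_trials.size < folds:
        raise ValueError("need at least `folds` training trials")
    meta_trial = features.meta["trial"].to_numpy()
    meta_bin = features.meta["bin"].to_numpy()
    n_bins = int(meta_bin.max()) + 1
    rng = np.random.default_rng(seed)
    conf_counts = np.zeros((n_bins, n_bins))
    same = test_trials is None or np.array_equal(
        np.sort(np.asarray(list(set(test_trials)))), train_trials)

    def _accumulate(tr_trials, te_trials):
        tr = np.isin(meta_trial, tr_trials)
        te = np.isin(meta_trial, te_trials)
        scaler, clf = _fit_svm(features.X[tr], meta_bin[tr], C,
                               multiclass=True)
        pred = clf.predict(scaler.transform(features.X[te]))
        for t, p in zip(meta_bin[te], pred):
            conf_counts[t, p] += 1

    if same:
        perm = rng.permutation(train_trials)
        parts = np.array_split(perm, folds)
        for k in range(folds):
            te_tr = parts[k]
            tr_tr = np.concatenate([parts[i] for i in range(folds) if i != k])
            _accumulate(tr_tr, te_tr)
    else:
        _accumulate(train_trials, np.asarray(sorted(set(test_trials))))
    support = conf_counts.sum(axis=1)
    conf = np.full_like(conf_counts, np.nan)
    rows = support > 0
    conf[rows] = conf_counts[rows] / support[rows, None]
    return TimeDecodeResult(confusion=conf, row_support=support,
                            bin_frames=bin_frames,
                            train_condition=train_condition,
                            test_condition=test_condition)


# -- auxiliary decoding variants ---------------------------------------

def subsample_curve(X, y, n_cells_list: Sequence[int], n_rep: int = 5,
                    seed: int = 0, **kw) -> pd.DataFrame:
    """Mean decoding accuracy vs number of cells, over random cell subsets."""
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_cells_list:
        if not (1 <= n <= X.shape[1]):
            raise ValueError(f"subset size {n} out of range")
        accs = []
        for _ in range(n_rep):
            cols = rng.choice(X.shape[1], size=n, replace=False)
            accs.append(decode_binary(X[:, cols], y,
                                      seed=int(rng.integers(2 ** 31)),
                                      **kw).accuracy)
        rows.append(dict(n_cells=int(n), accuracy=float(np.mean(accs)),
                         sd=float(np.std(accs))))
    return pd.DataFrame(rows)


def single_cell_decode(X, y, n_shuffle: int = 100, seed: int = 0,
                       **kw) -> pd.DataFrame:
    """Per-cell decoding accuracy with a per-cell shuffle null.

    Returns a frame with accuracy, the 99th-percentile null, and an
    ``above_chance`` flag per cell.
    """
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(X.shape[1]):
        res = decode_binary(X[:, [c]], y, n_shuffle=n_shuffle,
                            seed=int(rng.integers(2 ** 31)), **kw)
        thr = float(np.percentile(res.null_accuracies, 99))
        rows.append(dict(cell=c, accuracy=res.accuracy, null_99=thr,
                         above_chance=bool(res.accuracy > thr)))
    return pd.DataFrame(rows)


def subset_cells(features: FeatureMatrix, cell_mask) -> FeatureMatrix:
    cell_mask = np.asarray(cell_mask)
    if cell_mask.dtype == bool and not cell_mask.any():
        raise ValueError("empty cell subset")
    return FeatureMatrix(X=features.X[:, cell_mask], meta=features.meta.copy())


def trial_filter(features: FeatureMatrix, trial_range: tuple) -> FeatureMatrix:
    """Restrict samples to a trial-index range (e.g. session thirds)."""
    lo, hi = trial_range
    keep = ((features.meta["trial"] >= lo) &
            (features.meta["trial"] < hi)).to_numpy()
    if not keep.any():
        raise ValueError("trial filter leaves no samples")
    return FeatureMatrix(X=features.X[keep],
                         meta=features.meta[keep].reset_index(drop=True))
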