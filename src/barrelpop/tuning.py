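"""Time tuning via Skaggs information with a circular-shuffle threshold.

A cell's tuning curve is its per-bin transient probability across the
trial. Temporal information (bits per event) is the Skaggs metric

    I = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar)

with uniform occupancy p_i (every trial covers every bin) and
``lam_bar = sum_i p_i lam_i``. A cell is time-tuned when its information
exceeds the 95th percentile of informations from circularly shuffled
rasters; for tuned cells, the tuned *regions* are the maximal runs of bins
where the observed curve exceeds the pointwise 95th percentile of the
shuffled curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .classify import circular_shuffle_null


def skaggs_information(rates, occupancy=None) -> float:
    """Skaggs information (bits per event) of a binned rate curve."""
    rates = np.asarray(rates, dtype=float)
    if occupancy is None:
        occupancy = np.full(rates.shape, 1.0 / rates.size)
    occupancy = np.asarray(occupancy, dtype=float)
    if np.any(rates < 0) or np.any(occupancy < 0):
        raise ValueError("rates and occupancy must be non-negative")
    if not np.isclose(occupancy.sum(), 1.0):
        raise ValueError("occupancy must sum to 1")
    lam_bar = float(np.sum(occupancy * rates))
    if lam_bar == 0:
        return float("nan")
    ratio = rates / lam_bar
    terms = np.where(ratio > 0, occupancy * ratio * np.log2(
        np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def _info_rows(rate_matrix: np.ndarray) -> np.ndarray:
    """Row-wise Skaggs information with uniform occupancy (vectorized)."""
    n_bins = rate_matrix.shape[1]
    lam_bar = rate_matrix.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam_bar > 0, rate_matrix / lam_bar, 0.0)
        terms = np.where(ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    out = terms.sum(axis=1) / n_bins
    out[lam_bar.ravel() == 0] = np.nan
    return out


@dataclass
class TuningResult:
    information: float               # bits/event; NaN for event-free cells
    threshold: float                 # 95th percentile of shuffled information
    tuned: bool
    tuning_curve: np.ndarray         # per-bin transient probability
    regions: list                    # [(start_bin, stop_bin)] half-open
    region_times: list               # [(t0_s, t1_s)] trial-relative


def detect_time_tuning(raster: np.ndarray, bin_frames: int = 10,
                       n_shuffle: int = 1000, seed: int = 0,
                       frame_times: Optional[np.ndarray] = None,
                       rng: Optional[np.random.Generator] = None) -> TuningResult:
    """Time-tuning test for one cell's (trials x window-frames) raster."""
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    n_trials, n_frames = raster.shape
    n_bins = n_frames // bin_frames
    used = n_bins * bin_frames
    if rng is None:
        rng = np.random.default_rng(seed)

    def _binned(curves):
        return curves[..., :used].reshape(*curves.shape[:-1], n_bins,
                                          bin_frames).sum(axis=-1)

    curve = _binned(raster.mean(axis=0))
    null_curves = _binned(circular_shuffle_null(raster, n_iter=n_shuffle,
                                                rng=rng))
    info = float(_info_rows(curve[None, :])[0])
    null_info = _info_rows(null_curves)
    threshold = float(np.nanpercentile(null_info, 95)) \
        if np.any(np.isfinite(null_info)) else float("nan")
    tuned = bool(np.isfinite(info) and np.isfinite(threshold)
                 and info > threshold)
    regions, region_times = [], []
    if tuned:
        envelope = np.percentile(null_curves, 95, axis=0)
        above = curve > envelope
        start = None
        for b in range(n_bins + 1):
            on = b < n_bins and above[b]
            if on and start is None:
                start = b
            elif not on and start is not None:
                regions.append((start, b))
                start = None
        if frame_times is None:
            frame_times = np.arange(n_frames)
        for (b0, b1) in regions:
            region_times.append((float(frame_times[b0 * bin_frames]),
                                 float(frame_times[min(b1 * bin_frames,
                                                       n_frames - 1)])))
    return TuningResult(information=info, threshold=threshold, tuned=tuned,
                        tuning_curve=curve, regions=regions,
                        region_times=region_times)


def detect_time_tuning_all(rasters, bin_frames: int = 10,
                           n_shuffle: int = 1000, seed: int = 0,
                           frame_times=None) -> list:
    rng = np.random.default_rng(seed)
    return [detect_time_tuning(r, bin_frames=bin_frames, n_shuffle=n_shuffle,
                               frame_times=frame_times, rng=rng)
            for r in rasters]


def tuned_region_histogram(results, n_bins: int) -> np.ndarray:
    """Per time bin, the number of cells whose tuned regions cover it."""
    hist = np.zeros(n_bins, dtype=int)
    for res in results:
        covered = np.zeros(n_bins, dtype=bool)
        for (b0, b1) in res.regions:
            covered[b0:b1] = True
        hist += covered
    return hist
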