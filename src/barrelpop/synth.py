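"""Synthetic session generator with planted ground truth.

Emulates the statistical structure of a Pavlovian whisker-based
object-detection session recorded with a fast calcium indicator at 30 Hz:

* a trial clock (object enters at t=0, stops at 0.5 s, departs at 2.5 s,
  reward 0.407 s after departure on stimulus-present trials);
* a mixture of planted cell classes -- "on" cells emitting transients in
  [0, 1) s of stimulus trials, "off" cells in [depart, depart+1), "on-off"
  cells in both, "reward" cells in [reward, reward+1) of rewarded trials,
  and "none" cells firing only at a Poisson baseline rate;
* optional time cells emitting at a preferred trial time with Gaussian
  jitter, so that populations of them tile the trial;
* GCaMP6f-like traces: planted impulses convolved with a peak-normalized
  double-exponential kernel, on a constant baseline with white noise;
* learning-stage-dependent anticipatory licking, whisking bouts, cross-day
  affine image/ROI perturbations, and delayed-offset trials with planted
  response amplification.

Every generator is deterministic under a fixed seed, and returns a
:class:`GroundTruth` recording exactly what was planted so downstream
analyses can be verified end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session import (DEPART_T, REWARD_DELAY, STOP_T, AnalysisWindow,
                      Session, make_trial_table)

CELL_TYPES = ("on", "off", "on_off", "reward", "none")
RESPONSIVE_TYPES = ("on", "off", "on_off", "reward")

#: planted class mixtures (on, off, on_off, reward, none) by training stage
MIXTURES = {
    "naive": (0.15, 0.10, 0.10, 0.05, 0.60),
    "expert": (0.35, 0.20, 0.15, 0.05, 0.25),
}
#: P(anticipatory lick | stimulus), P(lick | no stimulus) by stage
LICK_MODELS = {"naive": (0.8, 0.8), "expert": (0.9, 0.15)}


class ConfigError(ValueError):
    """A simulation configuration violates its constraints."""


@dataclass
class SimConfig:
    """Parameters of one synthetic session.

    Defaults follow the task statistics a typical session shows: 116 cells,
    180 trials, half of them stimulus-present, with class mixtures that
    shift from mostly unresponsive (naive) to mostly touch-driven (expert).
    """

    n_cells: int = 116
    n_trials: int = 180
    stimulus_fraction: float = 0.5
    stage: str = "expert"
    cell_type_probs: Optional[Sequence[float]] = None  # over CELL_TYPES
    time_cell_fraction: float = 0.15
    time_sigma_s: float = 0.08       # tuning jitter of time cells
    time_cell_range: tuple = (0.0, 4.0)
    time_cell_tiling: bool = False   # evenly spaced tuned times vs uniform draw
    event_prob: float = 0.7          # transients per preferred event window
    baseline_rate: float = 0.02      # transients per frame, all cells
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.4
    amplitude_sd: float = 5.0        # kernel peak, units of noise SD
    noise_sd: float = 10.0           # raw fluorescence units
    baseline_f: float = 100.0        # raw fluorescence baseline
    lick_p_stim: Optional[float] = None
    lick_p_nostim: Optional[float] = None
    anticip_lick_rate_hz: float = 5.0
    whisk_bout_rate_hz: float = 0.15
    whisk_stim_locked_p: float = 0.3
    motion_rate: float = 125.0
    trial_period_s: float = 8.0
    frame_rate: float = 30.0
    image_size: int = 256
    roi_radius_px: float = 4.0
    cohort: str = "conditioned"

    def __post_init__(self):
        if self.cell_type_probs is None:
            self.cell_type_probs = MIXTURES[self.stage]
        if self.lick_p_stim is None:
            self.lick_p_stim = LICK_MODELS[self.stage][0]
        if self.lick_p_nostim is None:
            self.lick_p_nostim = LICK_MODELS[self.stage][1]
        self.validate()

    def validate(self):
        p = np.asarray(self.cell_type_probs, dtype=float)
        if p.shape != (5,) or abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
            raise ConfigError("cell_type_probs must be 5 non-negative values summing to 1")
        for name in ("event_prob", "baseline_rate", "rise_tau_s", "decay_tau_s",
                     "time_sigma_s", "frame_rate", "trial_period_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 <= self.stimulus_fraction <= 1):
            raise ConfigError("stimulus_fraction must lie in [0, 1]")
        if not (0 <= self.time_cell_fraction <= 1):
            raise ConfigError("time_cell_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.stage == "expert":
            # expected fraction correct from the lick model alone
            perf = (self.stimulus_fraction * self.lick_p_stim
                    + (1 - self.stimulus_fraction) * (1 - self.lick_p_nostim))
            if perf <= 0.7:
                raise ConfigError(
                    f"expert lick model implies performance {perf:.2f} <= 0.7")

    @property
    def expected_performance(self) -> float:
        return (self.stimulus_fraction * self.lick_p_stim
                + (1 - self.stimulus_fraction) * (1 - self.lick_p_nostim))


@dataclass
class GroundTruth:
    """What was planted: per-cell class, tuning, events, and identities."""

    cell_types: np.ndarray               # (n_cells,) str
    time_cell: np.ndarray                # (n_cells,) bool
    tuned_time: np.ndarray               # (n_cells,) float, NaN if not tuned
    event_frames: list                   # per cell, planted onset frames
    planted_lick: np.ndarray             # (n_trials,) bool
    surprise_amplified: np.ndarray       # (n_cells,) bool
    amplification: float = 1.0
    identity_maps: Optional[list] = None  # per session pair: [(i_prev, i_next)]
    affines: Optional[list] = None        # per later session: planted params

    def to_json(self, path) -> None:
        obj = {
            "cell_types": [str(t) for t in self.cell_types],
            "time_cell": self.time_cell.astype(bool).tolist(),
            "tuned_time": [None if np.isnan(t) else float(t)
                           for t in self.tuned_time],
            "event_frames": [np.asarray(f).tolist() for f in self.event_frames],
            "planted_lick": self.planted_lick.astype(bool).tolist(),
            "surprise_amplified": self.surprise_amplified.astype(bool).tolist(),
            "amplification": self.amplification,
            "identity_maps": self.identity_maps,
            "affines": self.affines,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def calcium_kernel(frame_rate: float, rise_tau_s: float = 0.05,
                   decay_tau_s: float = 0.4, cutoff: float = 1e-12) -> np.ndarray:
    """Peak-normalized double-exponential indicator kernel.

    ``k(t) = exp(-t/tau_d) - exp(-t/tau_r)`` sampled at the imaging frame
    rate and truncated where the decay falls below ``cutoff`` of the peak.
    """
    t_max = decay_tau_s * np.log(1.0 / cutoff)
    t = np.arange(0.0, t_max, 1.0 / frame_rate)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    return k / k.max()


def _assign_counts(probs: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` cells over classes."""
    probs = np.asarray(probs, dtype=float)
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _assign_types(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = _assign_counts(config.cell_type_probs, config.n_cells)
    types = np.repeat(np.array(CELL_TYPES, dtype=object), counts)
    return rng.permutation(types)


def _trial_starts(config: SimConfig) -> tuple[np.ndarray, int]:
    period = int(round(config.trial_period_s * config.frame_rate))
    margin = int(round(2.0 * config.frame_rate))
    starts = margin + np.arange(config.n_trials) * period
    n_frames = int(starts[-1] + period + 4 * config.frame_rate) if len(starts) \
        else margin + period
    return starts.astype(np.int64), n_frames


def _preferred_windows(cell_type: str, trial) -> list:
    """Trial-relative 1-s emission windows for a planted class."""
    wins = []
    if not trial.stimulus_present:
        return wins
    if cell_type in ("on", "on_off"):
        wins.append((0.0, 1.0))
    if cell_type in ("off", "on_off"):
        wins.append((trial.depart_t, trial.depart_t + 1.0))
    if cell_type == "reward" and not np.isnan(trial.reward_t):
        wins.append((trial.reward_t, trial.reward_t + 1.0))
    return wins


def _simulate_events(config: SimConfig, rng, types, time_cell, tuned_time,
                     trials, n_frames, amplified=None, amplification=1.0):
    """Planted transient onsets per cell: (frames, amplitudes) lists."""
    fr = config.frame_rate
    all_frames, all_amps = [], []
    starts = trials["start_frame"].to_numpy()
    offset_amp = np.ones(len(types))
    if amplified is not None:
        offset_amp = np.where(amplified, amplification, 1.0)
    for c, ctype in enumerate(types):
        frames, amps = [], []
        # baseline Poisson-like background, every cell
        base = np.flatnonzero(rng.random(n_frames) < config.baseline_rate)
        frames.extend(base.tolist())
        amps.extend([1.0] * len(base))
        for trial in trials.itertuples():
            sf = starts[trial.Index]
            for (a, b) in _preferred_windows(ctype, trial):
                if rng.random() < config.event_prob:
                    t_rel = a + rng.random() * (b - a)
                    # floor keeps the event inside the half-open window
                    f = int(sf + int(np.floor(t_rel * fr)))
                    if 0 <= f < n_frames:
                        frames.append(f)
                        # offset-locked events carry the surprise factor on
                        # delayed trials only
                        is_offset = (a == trial.depart_t)
                        amp = (offset_amp[c]
                               if is_offset and trial.delayed_offset else 1.0)
                        amps.append(amp)
            if time_cell[c] and trial.stimulus_present:
                if rng.random() < config.event_prob:
                    t_rel = tuned_time[c] + rng.normal(0, config.time_sigma_s)
                    f = int(sf + round(t_rel * fr))
                    if 0 <= f < n_frames:
                        frames.append(f)
                        amps.append(1.0)
        order = np.argsort(frames)
        all_frames.append(np.asarray(frames, dtype=np.int64)[order])
        all_amps.append(np.asarray(amps, dtype=float)[order])
    return all_frames, all_amps


def _render_traces(config: SimConfig, rng, event_frames, event_amps,
                   n_frames) -> np.ndarray:
    kernel = calcium_kernel(config.frame_rate, config.rise_tau_s,
                            config.decay_tau_s)
    amp_raw = config.amplitude_sd * (config.noise_sd
                                     if config.noise_sd > 0 else 1.0)
    traces = np.empty((len(event_frames), n_frames))
    for c, (frames, amps) in enumerate(zip(event_frames, event_amps)):
        sig = np.zeros(n_frames)
        np.add.at(sig, frames, amps * amp_raw)
        sig = np.convolve(sig, kernel)[:n_frames]
        noise = rng.normal(0.0, config.noise_sd, n_frames) \
            if config.noise_sd > 0 else 0.0
        traces[c] = config.baseline_f + sig + noise
    return traces


def _simulate_licks(config: SimConfig, rng, trials):
    """Planted per-trial lick outcome plus lick-time point process."""
    lick = np.empty(len(trials), dtype=bool)
    times = []
    fr = config.frame_rate
    for trial in trials.itertuples():
        p = config.lick_p_stim if trial.stimulus_present else config.lick_p_nostim
        lick[trial.Index] = rng.random() < p
        t0 = trial.start_frame / fr
        if lick[trial.Index]:
            # anticipatory burst within the 2-s stationary window
            n = 1 + rng.poisson(config.anticip_lick_rate_hz * (trial.depart_t - STOP_T) - 1)
            times.extend((t0 + STOP_T
                          + rng.random(n) * (trial.depart_t - STOP_T)).tolist())
        if trial.stimulus_present and lick[trial.Index] and not np.isnan(trial.reward_t):
            n = rng.poisson(6.0)
            times.extend((t0 + trial.reward_t + rng.random(n) * 1.0).tolist())
    return lick, np.sort(np.asarray(times))


def _simulate_whisking(config: SimConfig, rng, trials, n_frames) -> np.ndarray:
    """Rectified smoothed bout process at the video frame rate."""
    dur_s = n_frames / config.frame_rate
    n = int(round(dur_s * config.motion_rate))
    trace = np.abs(rng.normal(0.0, 0.05, n))
    bout_times = []
    t = rng.exponential(1.0 / config.whisk_bout_rate_hz)
    while t < dur_s:
        bout_times.append(t)
        t += 0.5 + rng.exponential(1.0 / config.whisk_bout_rate_hz)
    for trial in trials.itertuples():
        if rng.random() < config.whisk_stim_locked_p:
            bout_times.append(trial.start_frame / config.frame_rate
                              + rng.random() * 0.2)
    bout_len = int(round(0.7 * config.motion_rate))
    envelope = np.hanning(bout_len)
    for bt in bout_times:
        i0 = int(round(bt * config.motion_rate))
        seg = slice(i0, min(i0 + bout_len, n))
        m = seg.stop - seg.start
        if m > 0:
            trace[seg] += envelope[:m] * np.abs(rng.normal(1.0, 0.2, m))
    return trace


def _make_rois(config: SimConfig, rng, centers=None):
    size = config.image_size
    r = config.roi_radius_px
    if centers is None:
        margin = int(3 * r) + 2
        centers = rng.uniform(margin, size - margin, size=(config.n_cells, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    masks, image = [], np.zeros((size, size))
    for (cy, cx) in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        masks.append(d2 <= r * r)
        image += np.exp(-d2 / (2 * r * r))
    # smooth background texture so affine estimation has structure
    from scipy.ndimage import gaussian_filter
    image += 0.3 * gaussian_filter(rng.normal(0, 1, (size, size)), 3.0)
    return masks, image, np.asarray(centers)


def _generate(config: SimConfig, rng, types=None, time_cell=None,
              tuned_time=None, centers=None, delayed=None,
              amplified=None, amplification=1.0, stage=None):
    if types is None:
        types = _assign_types(config, rng)
    n = config.n_cells
    if time_cell is None:
        k = int(round(config.time_cell_fraction * n))
        time_cell = np.zeros(n, dtype=bool)
        time_cell[rng.choice(n, size=k, replace=False)] = True
    if tuned_time is None:
        lo, hi = config.time_cell_range
        tuned_time = np.full(n, np.nan)
        idx = np.flatnonzero(time_cell)
        if idx.size:
            if config.time_cell_tiling:
                # evenly spaced centers so the population tiles the trial
                tuned_time[idx] = lo + (np.arange(idx.size) + 0.5) \
                    * (hi - lo) / idx.size
            else:
                tuned_time[idx] = rng.uniform(lo, hi, idx.size)
    starts, n_frames = _trial_starts(config)
    stim = rng.random(config.n_trials) < config.stimulus_fraction
    if delayed is None:
        delayed = np.zeros(config.n_trials, dtype=bool)
    trials = make_trial_table(starts, stim, delayed)
    if amplified is None:
        amplified = np.zeros(n, dtype=bool)
    event_frames, event_amps = _simulate_events(
        config, rng, types, time_cell, tuned_time, trials, n_frames,
        amplified=amplified, amplification=amplification)
    traces = _render_traces(config, rng, event_frames, event_amps, n_frames)
    planted_lick, lick_times = _simulate_licks(config, rng, trials)
    motion = _simulate_whisking(config, rng, trials, n_frames)
    masks, image, centers = _make_rois(config, rng, centers)
    session = Session(
        traces=traces, roi_masks=masks, mean_image=image, trials=trials,
        lick_times=lick_times, frame_rate=config.frame_rate,
        motion_trace=motion, motion_rate=config.motion_rate,
        cohort=config.cohort, stage=stage or config.stage)
    truth = GroundTruth(
        cell_types=np.asarray(types, dtype=object),
        time_cell=time_cell, tuned_time=tuned_time,
        event_frames=event_frames, planted_lick=planted_lick,
        surprise_amplified=amplified, amplification=amplification)
    return session, truth, centers


def generate_session(config: SimConfig, seed: int):
    """Generate one synthetic session; identical (config, seed) -> identical output."""
    rng = np.random.default_rng(seed)
    session, truth, _ = _generate(config, rng)
    return session, truth


def generate_delayed_offset_session(config: SimConfig, seed: int,
                                    delayed_fraction: float = 0.2,
                                    amplified_fraction: float = 0.32,
                                    amplification: float = 1.39):
    """Session where a random fraction of trials has the offset delayed by 1 s.

    Exactly ``round(amplified_fraction * n_cells)`` cells are marked as
    surprise-amplified: their offset-locked transient amplitude is
    multiplied by ``amplification`` on delayed trials only. Amplified cells
    are drawn preferentially from classes with an offset-locked response
    ("off", then "on-off"), since amplification acts on that response.
    "Off"-class cells always emit at the *actual* (shifted) offset.
    """
    if not (0.0 < delayed_fraction < 1.0):
        raise ConfigError("delayed_fraction must lie in (0, 1)")
    if amplification < 0:
        raise ConfigError("amplification must be >= 0")
    rng = np.random.default_rng(seed)
    types = _assign_types(config, rng)
    n_amp = int(round(amplified_fraction * config.n_cells))
    priority = np.concatenate([
        rng.permutation(np.flatnonzero(types == "off")),
        rng.permutation(np.flatnonzero(types == "on_off")),
        rng.permutation(np.flatnonzero(~np.isin(types, ("off", "on_off"))))])
    amplified = np.zeros(config.n_cells, dtype=bool)
    amplified[priority[:n_amp]] = True
    delayed = rng.random(config.n_trials) < delayed_fraction
    session, truth, _ = _generate(
        config, rng, types=types, delayed=delayed,
        amplified=amplified, amplification=amplification)
    return session, truth


def _rotation_affine(rot_deg: float, translation, scale: float):
    th = np.deg2rad(rot_deg)
    M = scale * np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
    return M, np.asarray(translation, dtype=float)


def generate_learning_series(config: SimConfig, n_sessions: int = 2,
                             overlap_fraction: float = 0.85,
                             rotation_max_deg: float = 5.0,
                             translation_max_px: float = 15.0,
                             scale_range: tuple = (0.95, 1.05),
                             centroid_jitter_px: float = 2.0,
                             u_to_r: float = 0.69, r_to_u: float = 0.17,
                             affines: Optional[list] = None,
                             seed: int = 0):
    """Longitudinal series of sessions sharing cells across days.

    Session 0 uses the naive class mixture; later sessions use the expert
    mixture obtained by pushing each shared cell through a responsive /
    unresponsive transition (``u_to_r``: P(unresponsive day k -> responsive
    day k+1); ``r_to_u`` the reverse). Later-day mean images and ROI
    centroids are the day-0 versions under a planted affine (day-k
    coordinates -> day-0 coordinates) plus per-ROI jitter.

    ``affines`` optionally fixes the planted transforms as a list of
    ``(rot_deg, (ty, tx), scale)`` per later session; each must respect the
    stated bounds.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ConfigError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def _draw_affine(i):
        if affines is not None:
            rot, tr, sc = affines[i]
        else:
            rot = rng.uniform(-rotation_max_deg, rotation_max_deg)
            tr = rng.uniform(-translation_max_px, translation_max_px, 2)
            sc = rng.uniform(*scale_range)
        if abs(rot) > rotation_max_deg + 1e-9:
            raise ConfigError(f"requested rotation {rot} deg exceeds bound "
                              f"{rotation_max_deg} deg")
        if np.max(np.abs(tr)) > translation_max_px + 1e-9:
            raise ConfigError("requested translation exceeds bound")
        if not (scale_range[0] - 1e-9 <= sc <= scale_range[1] + 1e-9):
            raise ConfigError("requested scale outside bounds")
        return float(rot), np.asarray(tr, dtype=float), float(sc)

    naive_cfg = dataclasses.replace(
        config, stage="naive", cell_type_probs=None,
        lick_p_stim=None, lick_p_nostim=None)
    expert_cfg = dataclasses.replace(
        config, stage="expert", cell_type_probs=None,
        lick_p_stim=None, lick_p_nostim=None)

    sessions, truths = [], []
    types0 = _assign_types(naive_cfg, rng)
    sess, truth, centers0 = _generate(naive_cfg, rng, types=types0)
    sess.session_index = 0
    sessions.append(sess)
    truths.append(truth)

    n = config.n_cells
    n_shared = int(round(overlap_fraction * n))
    prev_types, prev_centers = types0, centers0
    identity_maps, affine_params = [], []
    from scipy.ndimage import affine_transform as _at

    for s in range(1, n_sessions):
        rot, tr, sc = _draw_affine(s - 1)
        affine_params.append({"rot_deg": rot, "translation": tr.tolist(),
                              "scale": sc})
        M, t = _rotation_affine(rot, tr, sc)
        Minv = np.linalg.inv(M)
        shared_prev = np.sort(rng.choice(n, size=n_shared, replace=False))
        perm = rng.permutation(n)
        shared_new = perm[:n_shared]
        identity_maps.append([(int(a), int(b))
                              for a, b in zip(shared_prev, shared_new)])
        # class transition on the responsive/unresponsive axis
        new_types = np.array(_assign_types(expert_cfg, rng), dtype=object)
        resp_probs = np.asarray(expert_cfg.cell_type_probs[:4], dtype=float)
        resp_probs = resp_probs / resp_probs.sum()
        for a, b in zip(shared_prev, shared_new):
            was_resp = prev_types[a] != "none"
            if was_resp:
                new_types[b] = "none" if rng.random() < r_to_u else prev_types[a]
            else:
                if rng.random() < u_to_r:
                    new_types[b] = np.array(RESPONSIVE_TYPES, dtype=object)[
                        rng.choice(4, p=resp_probs)]
                else:
                    new_types[b] = "none"
        # geometry: day-k centers such that M @ c_k + t == c_prev (+ jitter)
        centers = np.empty((n, 2))
        margin = int(3 * config.roi_radius_px) + 2
        centers[:] = rng.uniform(margin, config.image_size - margin, (n, 2))
        for a, b in zip(shared_prev, shared_new):
            centers[b] = (Minv @ (prev_centers[a] - t)
                          + rng.uniform(-centroid_jitter_px,
                                        centroid_jitter_px, 2))
        sess, truth, centers = _generate(
            expert_cfg, rng, types=new_types, centers=centers)
        # mean image of the later day is the day-0 texture under the
        # planted affine, so registration sees consistent structure
        sess.mean_image = _at(sessions[0].mean_image, M, offset=t, order=1)
        sess.session_index = s
        sessions.append(sess)
        truths.append(truth)
        prev_types, prev_centers = new_types, centers

    for truth in truths:
        truth.identity_maps = identity_maps
        truth.affines = affine_params
    return list(zip(sessions, truths))
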