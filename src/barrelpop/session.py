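"""Shared data model and on-disk session container.

A :class:`Session` bundles everything one imaging session produces after
upstream motion correction and ROI extraction: the cell fluorescence matrix
(cells x frames, 30 Hz), ROI pixel masks and a mean image for longitudinal
registration, the trial table, lick events, and an optional whisker
motion-energy trace.

Conventions used throughout the package:

* frames are 0-based; times are seconds; intervals are half-open ``[a, b)``;
* trial-relative time ``t = 0`` is the moment the object *enters* the
  whisker field; it stops at 0.5 s, departs at 2.5 s (3.5 s on
  delayed-offset trials), and on stimulus-present trials a water reward is
  delivered 0.407 s after departure begins.

Sessions are stored in an HDF5 container (groups ``/traces``, ``/rois``,
``/mean_image``, ``/trials``, ``/behavior``, and root attributes for
metadata) so that they remain language-agnostic and randomly accessible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: seconds after trial start at which the moving object stops
STOP_T = 0.5
#: seconds after trial start at which the object departs (normal trials)
DEPART_T = 2.5
#: departure time on delayed-offset trials (offset delayed by 1 s)
DEPART_T_DELAYED = 3.5
#: latency from departure onset to reward-valve opening, seconds
REWARD_DELAY = 0.407

COHORTS = ("conditioned", "repeated_exposure")
STAGES = ("naive", "expert")
RESPONSE_LABELS = ("hit", "miss", "false_alarm", "correct_rejection")

TRIAL_COLUMNS = ("start_frame", "stimulus_present", "delayed_offset",
                 "depart_t", "reward_t")


class FormatError(ValueError):
    """The on-disk container is missing a required dataset or attribute."""


class ValidationError(ValueError):
    """A session (or trial table) violates a data-model invariant."""


def make_trial_table(start_frames, stimulus_present, delayed_offset=None,
                     response_label=None) -> pd.DataFrame:
    """Build a canonical trial table from per-trial flags.

    Departure and reward times are derived from the task structure:
    ``depart_t`` is 2.5 s (3.5 s if the offset is delayed) and ``reward_t``
    is ``depart_t + 0.407`` s on stimulus-present trials, NaN otherwise.
    """
    start_frames = np.asarray(start_frames, dtype=np.int64)
    stimulus_present = np.asarray(stimulus_present, dtype=bool)
    n = len(start_frames)
    if delayed_offset is None:
        delayed_offset = np.zeros(n, dtype=bool)
    delayed_offset = np.asarray(delayed_offset, dtype=bool)
    depart_t = np.where(delayed_offset, DEPART_T_DELAYED, DEPART_T)
    reward_t = np.where(stimulus_present, depart_t + REWARD_DELAY, np.nan)
    table = pd.DataFrame({
        "start_frame": start_frames,
        "stimulus_present": stimulus_present,
        "delayed_offset": delayed_offset,
        "depart_t": depart_t,
        "reward_t": reward_t,
    })
    if response_label is not None:
        table["response_label"] = list(response_label)
    return table


def validate_trials(trials: pd.DataFrame, n_frames: Optional[int] = None) -> None:
    """Raise :class:`ValidationError` if the trial table is inconsistent."""
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise FormatError(f"trial table missing column {col!r}")
    start = trials["start_frame"].to_numpy()
    if len(start) and not np.all(np.diff(start) > 0):
        idx = int(np.flatnonzero(np.diff(start) <= 0)[0])
        raise ValidationError(f"trials not sorted/strictly increasing at trial {idx + 1}")
    if n_frames is not None and len(start):
        bad = np.flatnonzero((start < 0) | (start >= n_frames))
        if bad.size:
            raise ValidationError(f"trial {int(bad[0])} start_frame outside [0, {n_frames})")
    expected_depart = np.where(trials["delayed_offset"], DEPART_T_DELAYED, DEPART_T)
    if not np.allclose(trials["depart_t"], expected_depart):
        idx = int(np.flatnonzero(~np.isclose(trials["depart_t"], expected_depart))[0])
        raise ValidationError(f"trial {idx}: depart_t inconsistent with delayed_offset flag")
    has_reward = trials["reward_t"].notna().to_numpy()
    stim = trials["stimulus_present"].to_numpy(dtype=bool)
    if np.any(has_reward != stim):
        idx = int(np.flatnonzero(has_reward != stim)[0])
        raise ValidationError(
            f"trial {idx}: reward_t must be present iff stimulus_present")
    rew = trials.loc[has_reward, "reward_t"].to_numpy()
    dep = trials.loc[has_reward, "depart_t"].to_numpy()
    if rew.size and not np.allclose(rew, dep + REWARD_DELAY):
        raise ValidationError("reward_t must equal depart_t + 0.407 s")
    if "response_label" in trials.columns:
        labels = trials["response_label"].dropna()
        bad = ~labels.isin(RESPONSE_LABELS)
        if bad.any():
            raise ValidationError(f"unknown response label {labels[bad].iloc[0]!r}")


@dataclass
class AnalysisWindow:
    """Trial-aligned analysis window, in seconds around object entry.

    ``pre_s`` seconds before t=0 and ``post_s`` after are extracted per
    trial; ``bin_frames`` frames per time bin (10 frames = 1/3 s at 30 Hz)
    with any trailing partial bin truncated.
    """

    pre_s: float = 1.0
    post_s: float = 5.0
    bin_frames: int = 10

    def __post_init__(self):
        if self.pre_s < 0 or self.post_s < 0:
            raise ValueError("pre_s and post_s must be >= 0")
        if self.bin_frames < 1:
            raise ValueError("bin_frames must be >= 1")

    def n_frames(self, frame_rate: float) -> int:
        return int(round((self.pre_s + self.post_s) * frame_rate))

    def pre_frames(self, frame_rate: float) -> int:
        return int(round(self.pre_s * frame_rate))

    def n_bins(self, frame_rate: float) -> int:
        return self.n_frames(frame_rate) // self.bin_frames

    def frame_slice(self, start_frame: int, frame_rate: float) -> slice:
        """Absolute frame slice for a trial starting at ``start_frame``."""
        lo = start_frame - self.pre_frames(frame_rate)
        return slice(lo, lo + self.n_frames(frame_rate))

    def frame_times(self, frame_rate: float) -> np.ndarray:
        """Trial-relative time (s) of each frame in the window."""
        return (np.arange(self.n_frames(frame_rate)) -
                self.pre_frames(frame_rate)) / frame_rate


DELAYED_WINDOW = AnalysisWindow(pre_s=1.0, post_s=6.0)


@dataclass
class Session:
    """One imaging session: traces, ROIs, trials, and behavior streams."""

    traces: np.ndarray                       # (n_cells, n_frames) float
    roi_masks: list                          # list of 2-D bool arrays
    mean_image: np.ndarray                   # 2-D float
    trials: pd.DataFrame
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    frame_rate: float = 30.0
    motion_trace: Optional[np.ndarray] = None
    motion_rate: float = 125.0
    mouse_id: str = "m0"
    session_index: int = 0
    cohort: str = "conditioned"
    stage: str = "naive"

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=np.float64)
        self.lick_times = np.asarray(self.lick_times, dtype=np.float64)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> None:
        if self.traces.ndim != 2:
            raise ValidationError("traces must be 2-D (cells x frames)")
        if not np.all(np.isfinite(self.traces)):
            raise ValidationError("traces contain non-finite values")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        if len(self.roi_masks) != self.n_cells:
            raise ValidationError(
                f"{len(self.roi_masks)} ROI masks for {self.n_cells} cells")
        if self.lick_times.size:
            if np.any(self.lick_times < 0):
                raise ValidationError("lick_times must be non-negative")
            if np.any(np.diff(self.lick_times) < 0):
                raise ValidationError("lick_times must be sorted")
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        validate_trials(self.trials, self.n_frames)

    def valid_trial_mask(self, window: AnalysisWindow) -> np.ndarray:
        """Trials whose analysis window lies fully inside the session.

        Out-of-bounds trials are excluded from trial-aligned analyses (and
        logged), never an error.
        """
        mask = np.ones(len(self.trials), dtype=bool)
        for i, sf in enumerate(self.trials["start_frame"]):
            sl = window.frame_slice(int(sf), self.frame_rate)
            if sl.start < 0 or sl.stop > self.n_frames:
                mask[i] = False
        n_bad = int((~mask).sum())
        if n_bad:
            logger.info("excluding %d trial(s) whose window exceeds session bounds", n_bad)
        return mask

    def equals(self, other: "Session") -> bool:
        """Field-by-field logical equality (used by round-trip tests)."""
        if self.traces.shape != other.traces.shape:
            return False
        same = (np.array_equal(self.traces, other.traces)
                and self.frame_rate == other.frame_rate
                and np.array_equal(self.mean_image, other.mean_image)
                and len(self.roi_masks) == len(other.roi_masks)
                and all(np.array_equal(a, b) for a, b in
                        zip(self.roi_masks, other.roi_masks))
                and np.array_equal(self.lick_times, other.lick_times)
                and self.mouse_id == other.mouse_id
                and self.session_index == other.session_index
                and self.cohort == other.cohort
                and self.stage == other.stage)
        if not same:
            return False
        if (self.motion_trace is None) != (other.motion_trace is None):
            return False
        if self.motion_trace is not None:
            if not (np.array_equal(self.motion_trace, other.motion_trace)
                    and self.motion_rate == other.motion_rate):
                return False
        a, b = self.trials, other.trials
        if set(a.columns) != set(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if x.dtype.kind == "f":
                if not np.allclose(x, y, equal_nan=True):
                    return False
            elif not np.array_equal(x, y):
                return False
        return True


# -- I/O ----------------------------------------------------------------

def write_session(session: Session, path) -> None:
    """Write a session container (HDF5); overwrites any existing file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("mean_image", data=session.mean_image)
        rois = f.create_group("rois")
        if session.roi_masks:
            rois.create_dataset(
                "masks", data=np.stack([np.asarray(m, dtype=bool)
                                        for m in session.roi_masks]))
        trials = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            trials.create_dataset(col, data=session.trials[col].to_numpy())
        if "response_label" in session.trials.columns:
            labels = session.trials["response_label"].fillna("").to_numpy()
            trials.create_dataset(
                "response_label",
                data=np.asarray(labels, dtype=h5py.string_dtype()))
        beh = f.create_group("behavior")
        beh.create_dataset("lick_times", data=session.lick_times)
        if session.motion_trace is not None:
            d = beh.create_dataset("motion_trace", data=session.motion_trace)
            d.attrs["motion_rate"] = session.motion_rate
        f.attrs.update({
            "frame_rate": session.frame_rate,
            "mouse_id": session.mouse_id,
            "session_index": session.session_index,
            "cohort": session.cohort,
            "stage": session.stage,
        })


def read_session(path) -> Session:
    """Read a session container; raises on missing datasets or bad invariants."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("traces", "mean_image", "rois", "trials", "behavior"):
            if name not in f:
                raise FormatError(f"container missing dataset/group {name!r}")
        traces = f["traces"][()]
        mean_image = f["mean_image"][()]
        if "masks" in f["rois"]:
            roi_masks = [m.astype(bool) for m in f["rois/masks"][()]]
        else:
            roi_masks = []
        tgrp = f["trials"]
        cols = {}
        for col in TRIAL_COLUMNS:
            if col not in tgrp:
                raise FormatError(f"trial table missing column {col!r}")
            cols[col] = tgrp[col][()]
        cols["stimulus_present"] = cols["stimulus_present"].astype(bool)
        cols["delayed_offset"] = cols["delayed_offset"].astype(bool)
        trials = pd.DataFrame(cols)
        if "response_label" in tgrp:
            labels = [s.decode() if isinstance(s, bytes) else s
                      for s in tgrp["response_label"][()]]
            trials["response_label"] = [s if s else None for s in labels]
        lick_times = f["behavior/lick_times"][()]
        motion_trace = None
        motion_rate = 125.0
        if "motion_trace" in f["behavior"]:
            motion_trace = f["behavior/motion_trace"][()]
            motion_rate = float(f["behavior/motion_trace"].attrs.get(
                "motion_rate", 125.0))
        attrs = dict(f.attrs)
    try:
        return Session(
            traces=traces, roi_masks=roi_masks, mean_image=mean_image,
            trials=trials, lick_times=lick_times,
            frame_rate=float(attrs.get("frame_rate", 30.0)),
            motion_trace=motion_trace, motion_rate=motion_rate,
            mouse_id=str(attrs.get("mouse_id", "m0")),
            session_index=int(attrs.get("session_index", 0)),
            cohort=str(attrs.get("cohort", "conditioned")),
            stage=str(attrs.get("stage", "naive")))
    except ValidationError:
        raise


def export_trials_csv(session: Session, path) -> None:
    session.trials.to_csv(path, index=False)


def export_meta_json(session: Session, path) -> None:
    import json
    meta = {
        "mouse_id": session.mouse_id,
        "session_index": session.session_index,
        "cohort": session.cohort,
        "stage": session.stage,
        "frame_rate": session.frame_rate,
        "n_cells": session.n_cells,
        "n_frames": session.n_frames,
        "n_trials": int(len(session.trials)),
    }
    Path(path).write_text(json.dumps(meta, indent=2))
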