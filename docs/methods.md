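# Methods

This note documents the models, parameters, and numerical choices behind
`barrelpop`, and what the synthetic-data tests do and do not establish
about real recordings.

## Task and session model

Trials follow the object-detection clock: object enters at *t* = 0, stops
at 0.5 s, departs at 2.5 s (3.5 s on delayed-offset trials), and reward
opens 0.407 s after departure on stimulus-present trials. Frames are
0-based at 30 Hz, times are seconds, and all intervals are half-open
[a, b). Trial-aligned analyses use a window of 1 s before to 5 s after
entry (6 s after for delayed-offset sessions), cut into 10-frame
(1/3-s) bins with any trailing partial bin truncated. Trials whose window
crosses a session edge are excluded from trial-aligned analyses and
logged, never an error.

## Synthetic sessions

The generator is the package's test bed: it produces sessions whose
*statistical* structure matches what the analyses assume, with every
planted quantity recorded in a `GroundTruth` object.

* **Cell classes.** Counts follow a largest-remainder apportionment of the
  class mixture (naive 15/10/10/5/60%, expert 35/20/15/5/25% for
  on/off/on-off/reward/none), so composition is deterministic given the
  configuration. "On" cells emit one transient with probability 0.7 per
  stimulus trial uniformly in [0, 1) s, "off" cells in [depart,
  depart + 1), "on-off" cells in both, "reward" cells in
  [reward, reward + 1) of rewarded trials; every cell also emits at a
  Poisson-like baseline of 0.02 per frame. Event frames use
  floor(t·rate) so an event never leaves its half-open window.
* **Traces.** Planted impulses are convolved with a peak-normalized
  double-exponential kernel (rise 0.05 s, decay 0.4 s — typical fast
  indicator values, configurable) with peak amplitude 5 noise-SD, on a
  constant baseline of 100 units with white noise of SD 10. With
  `noise_sd = 0` the amplitude is read in raw units so noiseless
  constructions remain meaningful.
* **Time cells.** An optional overlay: a fraction of cells (default 0.15)
  additionally emit at a preferred trial time with Gaussian jitter
  (σ = 0.08 s) on stimulus trials. Centers are drawn uniformly over the
  trial by default; `time_cell_tiling` spaces them evenly, which is how
  planted-sequence fixtures are built. Because the overlay makes the
  five-way planted label ambiguous, classification-recovery fixtures
  disable it.
* **Behavior.** Licking is planted per trial (naive 0.8/0.8,
  expert 0.9/0.15 for stimulus/no-stimulus), with an anticipatory burst
  in [0.5, depart) on lick trials; the expert model implies expected
  performance 0.875, validated analytically at configuration time.
  Whisking is a rectified smoothed bout process at 125 Hz with bouts at
  least 0.5 s apart, optionally stimulus-locked.
* **Longitudinal series.** Later-day geometry is the day-0 geometry under
  a planted affine (|rotation| ≤ 5°, |translation| ≤ 15 px,
  scale 0.95–1.05) plus ≤ 2 px per-ROI jitter; shared cells keep identity
  and change responsiveness by a 2 × 2 transition model (defaults: 69%
  unresponsive→responsive for conditioning, 17% the reverse). The
  later-day mean image is the day-0 texture warped by the planted affine,
  so registration sees consistent structure even as individual cells turn
  over.
* **Delayed offsets.** A random 20% of trials depart at 3.5 s.
  Exactly round(0.32 · n_cells) cells are marked surprise-amplified;
  their offset-locked transient amplitude is multiplied by 1.39 on
  delayed trials. Amplified cells are drawn from classes that have an
  offset-locked response ("off" first, then "on-off") because the
  amplification acts on that response. The surprise fixtures are
  generated all-stimulus so that every trial contributes an offset
  response.

What the generator does **not** emulate: shot-noise optics, neuropil
contamination, slow drift, correlated population noise, bursty
multi-amplitude transients, or whisker-contact-driven responses on
stimulus-absent trials. Passing tests therefore demonstrate correctness
of the *algorithms* under the planted statistical model, not robustness
to every artifact of real recordings.

## Signal processing

Raw traces are Savitzky–Golay smoothed (window 15 frames = 0.5 s,
polyorder 3). ΔF/F uses the 8th percentile of a 50-s
window centered on each frame (truncated at edges) as baseline; the
implementation maintains an incrementally sorted window, is exact (tested
frame-for-frame against a brute-force oracle), and refuses non-positive
baselines. Transients are threshold crossings of
median + 2 SD of the cell's full-session ΔF/F: onset at the first frame
strictly above, offset at the first frame at or below, no debouncing.

Two numerical points drove the defaults. First, at 0.5-s smoothing the
kernel peak is attenuated by under 5% while threshold "chatter" (spurious
re-crossings as a decaying transient wanders around the threshold) is
suppressed; with light smoothing chatter dominates false detections at
any threshold. Second, the full-session SD deliberately includes
transient variance: on sparse traces this lifts the threshold to ~3.5
smoothed-noise SD, which is what keeps the false-onset rate low. The
flip side is that densely active cells raise their own threshold and can
absorb single events into ongoing elevations; robust (MAD-based) SD
estimators were evaluated and rejected because they collapse precision
on sparse cells.

## Classification

Per cell, a binary raster marks transient-onset frames across
stimulus-present trials (the events that define the categories exist only
there; a `trial_subset` switch restores all trials). The probability
curve is the column mean; the null is 5000 circular shuffles in which
every trial row is independently rotated by a uniform offset, conserving
per-trial counts and autocorrelation exactly. The statistic per window
(onset [0, 1), offset [2.5, 3.5), reward [3.5, 4.5) — the reward window
is placed after the offset window so the two are disjoint) is the mean
probability over window frames; z = (obs − null mean)/null SD with a
one-sided normal p (excess only), Benjamini–Hochberg corrected across
all cells × windows at α = 0.05. Labels follow a fixed rule on the three
significance flags: onset∧offset → on-off; reward∧¬onset → reward (this
precedence makes reward cells, whose response straddles the offset
window, recoverable); else onset → on, offset → off, nothing → none.

## Decoding

Features are integer counts of transient onsets per cell, per trial over
[0, 4) s (stimulus/choice) or per (trial, 10-frame bin) (time). Binary
decoding is a linear SVM (C = 1) with standardized features under 4-fold
stratified cross-validation; class balancing by random subsampling
(default, the trial-matching approach) or by weights inverse to the
stimulus × choice cell frequency (trial balancing). Separability is the
1-D earth mover's distance between class projections on the unit coding
axis fit on all (balanced) samples. Per-bin timecourses call the binary
decoder independently per bin; a bin is significant when its accuracy
exceeds the 99th percentile of its own label-permutation null, and the
first significant bin uses the single-bin rule (a
`require_consecutive` option guards against isolated false positives).

Time decoding treats bin identity as a multi-class target. Folds are
over *trials* to avoid leakage between bins of one trial; cross-condition
evaluation (e.g. train on hit, test on miss) trains on all
train-condition trials. The classifier is the joint multi-class linear
SVM (Crammer–Singer): with 18 classes and sparse count features,
independent one-vs-rest scores calibrate against each other poorly
(mean absolute error 1.4 bins on a planted tiling sequence versus 0.9
for the joint formulation). Confusion matrices are row-normalized over
true bins; rows with no test samples are reported as missing (NaN), not
zero-filled.

## Temporal tuning

The tuning curve is the per-bin transient probability. Skaggs
information I = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄) uses uniform occupancy (every
trial covers every bin), with 0·log 0 ≡ 0 and an undefined (NaN) value
for event-free cells. A cell is time-tuned when its information exceeds
the 95th percentile of 1000 circular-shuffle informations; tuned regions
are maximal bin runs where the observed curve exceeds the pointwise 95th
percentile of shuffled curves, computed only for tuned cells.

## Movement controls

Motion energy is the ROI-mean absolute difference of consecutive video
frames (125 Hz), aligned to the imaging clock by linear interpolation.
Bouts reuse the transient threshold rule (median + 2 SD) with a 0.5-s
minimum separation. Event regression convolves task-event delta trains
with the calcium kernel, z-scores continuous regressors, fits ordinary
least squares per cell, and rejects rank-deficient designs naming the
collinear columns. Behavioral time decoding feeds per-bin whisking
energy, lick counts, and event indicators through the same time decoder.

## Temporal surprise

Per trial, the late-peak amplitude is the maximum ΔF/F in
[depart, depart + 1) — each trial's own departure — minus the mean over
the 0.5 s before departure, making the measure invariant to trace
offsets. Per cell, normal vs delayed amplitudes are compared by a
two-sided rank-sum test with Benjamini–Hochberg correction across cells;
the population test is a Wilcoxon signed-rank on per-cell mean pairs;
relative change is (mean_delayed − mean_normal)/mean_normal. The
off-cell re-locking check finds the peak latency of the trial-averaged
response in a common search window ([1.5, 5.9) s) for both conditions
and reports the median shift.

A power note: at the generator's default baseline rate (0.02
transients/frame), baseline events landing inside the 1-s offset window
add amplitude variability comparable to the planted 1.39× shift, so
per-cell sensitivity at 40 delayed trials is limited (~0.3–0.5); the
identical pipeline reaches sensitivity above 0.8 on sparser cells
(baseline 0.002/frame). The relative-change estimate is mildly diluted
toward ~0.3 by the 30% of trials without a planted offset event.

## Longitudinal tracking

Registration maximizes the Pearson correlation between the day-A mean
image and the warped day-B image over a 6-parameter affine (rotation,
log-scales, shear, translation), coarse-to-fine over a 4×/2×/1× pyramid,
Powell search, initialized by phase-correlation translation. It recovers
a planted 3° + (5, −7) px transform to better than 0.1° and 0.1 px on
blob images. Warped ROI masks (nearest-neighbor) are matched by IoU with
a 0.3 minimum, assigned greedily by descending score (an ROI pairs with
the ROI it overlaps most); ROIs in two or more candidate pairs can be
excluded as "double overlaps". Registries chain matches transitively;
when two chains would merge, the higher cumulative-score chain keeps the
label. Transition matrices are row-normalized over day-1 states.

## Problem sizes and determinism

Every stochastic step takes a seed and is bit-reproducible. Test and
acceptance fixtures use 116-cell, 180-trial sessions for classification
and time decoding, 50-cell, 200-trial all-stimulus sessions for the
delayed-offset analysis, 40-cell two-day series on 192² images for
tracking, and smaller sessions for unit tests; these sizes match the
study's per-session scale while keeping the full suite to a few minutes
of CPU.
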