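"""Longitudinal cell tracking across sessions.

The same field of view is imaged on consecutive days; to identify the same
cells, the later day's mean image is registered to the earlier day's with a
6-parameter affine transform (intensity-based, maximizing image
correlation with a multi-resolution search), the same transform is applied
to every ROI mask, and warped ROIs are matched to the reference day's ROIs
by degree of pixel overlap (intersection-over-union by default). Matched
ROIs receive a persistent label, which chains transitively across
additional sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation


class RegistrationError(RuntimeError):
    """Affine estimation failed; carries the best transform found so far."""

    def __init__(self, message, transform=None, criterion=None):
        super().__init__(message)
        self.transform = transform
        self.criterion = criterion


@dataclass
class AffineTransform:
    """Maps day-B pixel coordinates into day-A coordinates: x_A = M x_B + t."""

    matrix: np.ndarray        # (2, 2)
    translation: np.ndarray   # (2,), (row, col)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.matrix)) <= 1e-6:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def inverse(self) -> "AffineTransform":
        Minv = np.linalg.inv(self.matrix)
        return AffineTransform(Minv, -Minv @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.matrix.T + self.translation

    def warp_to_a(self, image_b: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample a day-B image onto the day-A grid."""
        inv = self.inverse()
        return ndimage.affine_transform(
            np.asarray(image_b, dtype=float), inv.matrix, offset=inv.translation,
            order=order, mode="constant", cval=0.0)

    def warp_mask_to_a(self, mask_b: np.ndarray) -> np.ndarray:
        return self.warp_to_a(np.asarray(mask_b, dtype=float), order=0) > 0.5


def _params_to_transform(p) -> AffineTransform:
    ang, lsy, lsx, shear, ty, tx = p
    th = np.deg2rad(ang)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    S = np.diag([np.exp(lsy), np.exp(lsx)])
    H = np.array([[1.0, shear], [0.0, 1.0]])
    return AffineTransform(R @ S @ H, np.array([ty, tx]))


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, factor / 2.0)
    return sm[::factor, ::factor]


def _neg_correlation(p, a, b, factor):
    tr = _params_to_transform([p[0], p[1], p[2], p[3],
                               p[4] / factor, p[5] / factor])
    warped = tr.warp_to_a(b)
    valid = tr.warp_to_a(np.ones_like(b)) > 0.5
    if valid.sum() < 0.25 * valid.size:
        return 1.0
    x, y = a[valid], warped[valid]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 1.0
    return -float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def estimate_affine(mean_image_a, mean_image_b, levels=(4, 2, 1),
                    min_correlation: float = 0.2) -> AffineTransform:
    """Estimate the affine mapping day-B coordinates into day-A coordinates.

    Intensity-based: maximizes the Pearson correlation between the day-A
    image and the warped day-B image, coarse-to-fine over a resolution
    pyramid, initialized with a phase-correlation translation estimate.
    Returns the transform; raises :class:`RegistrationError` (carrying the
    best transform found) if the final correlation stays below
    ``min_correlation``.
    """
    a = np.asarray(mean_image_a, dtype=float)
    b = np.asarray(mean_image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a pixel grid")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant image: affine estimation is undefined")
    shift = phase_cross_correlation(a, b, normalization=None)[0]
    p = np.array([0.0, 0.0, 0.0, 0.0, float(shift[0]), float(shift[1])])
    for factor in levels:
        aa, bb = _downsample(a, factor), _downsample(b, factor)
        res = optimize.minimize(
            _neg_correlation, p, args=(aa, bb, factor), method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 2000})
        p = res.x
    tr = _params_to_transform(p)
    corr = -_neg_correlation(p, a, b, 1)
    tr.criterion = corr
    if corr < min_correlation:
        raise RegistrationError(
            f"registration correlation {corr:.3f} below {min_correlation}",
            transform=tr, criterion=corr)
    return tr


@dataclass
class TrackingMap:
    """ROI matching between two sessions (a partial bijection)."""

    pairs: list                      # (cell_a, cell_b, score)
    unmatched_a: list
    unmatched_b: list
    double_overlap_count: int
    transform: Optional[AffineTransform] = None

    @property
    def matched_a(self):
        return [p[0] for p in self.pairs]

    @property
    def matched_b(self):
        return [p[1] for p in self.pairs]


def _overlap(mask_a, mask_b, metric: str) -> float:
    inter = np.logical_and(mask_a, mask_b).sum()
    if inter == 0:
        return 0.0
    if metric == "iou":
        return float(inter / np.logical_or(mask_a, mask_b).sum())
    if metric == "min":
        return float(inter / min(mask_a.sum(), mask_b.sum()))
    raise ValueError(f"unknown overlap metric {metric!r}")


def match_rois(masks_a, masks_b, transform: AffineTransform,
               min_overlap: float = 0.3, exclude_double_overlap: bool = False,
               metric: str = "iou") -> TrackingMap:
    """Match day-B ROIs (warped into A-space) to day-A ROIs by overlap.

    Candidate pairs with overlap >= ``min_overlap`` are assigned greedily in
    descending score, so each ROI pairs with the ROI it overlaps most. With
    ``exclude_double_overlap`` any ROI appearing in two or more candidate
    pairs is dropped before assignment (control for ambiguous merges).
    """
    warped = [transform.warp_mask_to_a(m) for m in masks_b]
    candidates = []
    for j, wm in enumerate(warped):
        if not wm.any():
            continue
        for i, ma in enumerate(masks_a):
            score = _overlap(ma, wm, metric)
            if score >= min_overlap:
                candidates.append((i, j, score))
    if exclude_double_overlap:
        from collections import Counter
        ca = Counter(c[0] for c in candidates)
        cb = Counter(c[1] for c in candidates)
        dropped_a = {i for i, k in ca.items() if k >= 2}
        dropped_b = {j for j, k in cb.items() if k >= 2}
        n_double = len(dropped_a) + len(dropped_b)
        candidates = [c for c in candidates
                      if c[0] not in dropped_a and c[1] not in dropped_b]
    else:
        from collections import Counter
        ca = Counter(c[0] for c in candidates)
        cb = Counter(c[1] for c in candidates)
        n_double = (sum(1 for k in ca.values() if k >= 2)
                    + sum(1 for k in cb.values() if k >= 2))
    pairs, used_a, used_b = [], set(), set()
    for i, j, score in sorted(candidates, key=lambda c: -c[2]):
        if i not in used_a and j not in used_b:
            pairs.append((i, j, score))
            used_a.add(i)
            used_b.add(j)
    return TrackingMap(
        pairs=pairs,
        unmatched_a=[i for i in range(len(masks_a)) if i not in used_a],
        unmatched_b=[j for j in range(len(masks_b)) if j not in used_b],
        double_overlap_count=n_double,
        transform=transform)


def build_registry(tracking_maps, n_cells_per_session) -> pd.DataFrame:
    """Chain consecutive-session matches into persistent cell labels.

    Returns a long DataFrame (session, cell, label): a cell matched across
    sessions i and i+1 keeps one label; if two chains would merge onto the
    same cell the higher cumulative-score chain wins and the loser starts a
    new label.
    """
    labels = [dict() for _ in n_cells_per_session]
    scores = [dict() for _ in n_cells_per_session]
    next_label = 0
    for c in range(n_cells_per_session[0]):
        labels[0][c] = next_label
        scores[0][c] = 0.0
        next_label += 1
    for s, tmap in enumerate(tracking_maps):
        claimed = {}
        for i, j, score in sorted(tmap.pairs, key=lambda p: -p[2]):
            lab = labels[s].get(i)
            if lab is None:
                continue
            cum = scores[s][i] + score
            if lab in claimed.values():
                continue
            claimed[j] = lab
            labels[s + 1][j] = lab
            scores[s + 1][j] = cum
        for c in range(n_cells_per_session[s + 1]):
            if c not in labels[s + 1]:
                labels[s + 1][c] = next_label
                scores[s + 1][c] = 0.0
                next_label += 1
    rows = [dict(session=s, cell=c, label=lab)
            for s, d in enumerate(labels) for c, lab in d.items()]
    return pd.DataFrame(rows)


def tracked_pairs(registry: pd.DataFrame, session_a: int,
                  session_b: int) -> list:
    """(cell_a, cell_b) pairs sharing a label between two sessions."""
    a = registry[registry["session"] == session_a].set_index("label")["cell"]
    b = registry[registry["session"] == session_b].set_index("label")["cell"]
    common = a.index.intersection(b.index)
    return [(int(a[l]), int(b[l])) for l in common]


RESPONSIVE_GROUPING = {"responsive": ("on", "off", "on_off", "reward"),
                       "unresponsive": ("none",)}


def responsiveness_transitions(pairs, labels_a, labels_b,
                               grouping=None) -> pd.DataFrame:
    """Row-normalized transition fractions between day-A and day-B states.

    ``pairs`` are tracked (cell_a, cell_b) indices; ``labels_x`` the
    per-cell classification labels of each day. With the default grouping,
    labels collapse to responsive/unresponsive; pass
    ``grouping={l: (l,) for l in labels}`` for the full per-class matrix.
    """
    if len(pairs) == 0:
        raise ValueError("no tracked cells")
    if grouping is None:
        grouping = RESPONSIVE_GROUPING
    to_group = {lab: g for g, labs in grouping.items() for lab in labs}
    states = list(grouping)
    counts = pd.DataFrame(0.0, index=states, columns=states)
    for a, b in pairs:
        ga = to_group[labels_a[a] if not hasattr(labels_a[a], "label")
                      else labels_a[a].label]
        gb = to_group[labels_b[b] if not hasattr(labels_b[b], "label")
                      else labels_b[b].label]
        counts.loc[ga, gb] += 1
    row_sums = counts.sum(axis=1)
    out = counts.copy()
    for s in states:
        if row_sums[s] > 0:
            out.loc[s] = counts.loc[s] / row_sums[s]
    return out
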