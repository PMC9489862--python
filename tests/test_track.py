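"""Longitudinal tracking: affine estimation, ROI matching, transitions."""

import numpy as np
import pytest

from barrelpop.track import (AffineTransform, RegistrationError,
                             build_registry, estimate_affine, match_rois,
                             responsiveness_transitions, tracked_pairs)


def blob_image(centers, size=128, sigma=3.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for cy, cx in centers:
        img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    from scipy.ndimage import gaussian_filter
    img += 0.2 * gaussian_filter(rng.normal(0, 1, (size, size)), 2.0)
    return img


def disk_mask(cy, cx, size=128, r=4.0):
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestAffine:
    def test_identity_on_identical_images(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(20, 108, (25, 2))
        img = blob_image(centers)
        tr = estimate_affine(img, img)
        assert np.linalg.norm(tr.matrix - np.eye(2)) < 1e-2
        assert np.linalg.norm(tr.translation) < 0.5

    def test_recovers_planted_rotation_translation(self):
        from scipy.ndimage import affine_transform
        rng = np.random.default_rng(2)
        centers = rng.uniform(20, 108, (30, 2))
        img_a = blob_image(centers, seed=3)
        th = np.deg2rad(3.0)
        M = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.array([5.0, -7.0])
        img_b = affine_transform(img_a, M, offset=t, order=1)
        tr = estimate_affine(img_a, img_b)
        assert abs(tr.rotation_deg - 3.0) < 0.5
        assert np.abs(tr.translation - t).max() < 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_affine(np.ones((64, 64)), np.ones((64, 64)))

    def test_singular_linear_part_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((2, 2)), np.zeros(2))

    def test_round_trip_mask_iou(self):
        tr = AffineTransform(
            np.array([[np.cos(0.05), -np.sin(0.05)],
                      [np.sin(0.05), np.cos(0.05)]]), np.array([3.0, -2.0]))
        mask = disk_mask(60, 70, r=6)
        back = tr.inverse().warp_mask_to_a(tr.warp_mask_to_a(mask))
        inter = np.logical_and(mask, back).sum()
        union = np.logical_or(mask, back).sum()
        assert inter / union >= 0.95


class TestMatching:
    def test_identical_masks_identity_transform(self):
        masks = [disk_mask(30, 30), disk_mask(60, 80), disk_mask(100, 40)]
        tmap = match_rois(masks, masks, AffineTransform.identity())
        assert len(tmap.pairs) == 3
        assert all(s == pytest.approx(1.0) for _, _, s in tmap.pairs)
        assert [a == b for a, b, _ in tmap.pairs]

    def test_greatest_overlap_wins(self):
        # b overlaps a1 strongly and a2 weakly -> matched to a1
        a1, a2 = disk_mask(50, 50, r=6), disk_mask(50, 62, r=6)
        b = disk_mask(50, 52, r=6)
        tmap = match_rois([a1, a2], [b], AffineTransform.identity(),
                          min_overlap=0.01)
        assert tmap.pairs[0][:2] == (0, 0)
        assert tmap.double_overlap_count >= 1

    def test_exclude_double_overlap_drops_ambiguous(self):
        a1, a2 = disk_mask(50, 50, r=6), disk_mask(50, 58, r=6)
        b = disk_mask(50, 54, r=6)
        tmap = match_rois([a1, a2], [b], AffineTransform.identity(),
                          min_overlap=0.05, exclude_double_overlap=True)
        assert len(tmap.pairs) == 0
        assert 0 in tmap.unmatched_b

    def test_partial_bijection(self):
        rng = np.random.default_rng(4)
        centers = rng.uniform(15, 113, (20, 2))
        masks = [disk_mask(cy, cx) for cy, cx in centers]
        tmap = match_rois(masks, masks[5:], AffineTransform.identity())
        assert len(set(tmap.matched_a)) == len(tmap.pairs)
        assert len(set(tmap.matched_b)) == len(tmap.pairs)


class TestRegistry:
    def _map(self, pairs):
        from barrelpop.track import TrackingMap
        return TrackingMap(pairs=[(a, b, 1.0) for a, b in pairs],
                           unmatched_a=[], unmatched_b=[],
                           double_overlap_count=0)

    def test_two_sessions(self):
        reg = build_registry([self._map([(0, 1), (1, 0), (2, 2)])], [3, 3])
        pairs = tracked_pairs(reg, 0, 1)
        assert sorted(pairs) == [(0, 1), (1, 0), (2, 2)]

    def test_transitivity_three_sessions(self):
        reg = build_registry([self._map([(0, 2)]), self._map([(2, 1)])],
                             [3, 3, 3])
        assert tracked_pairs(reg, 0, 2) == [(0, 1)]


class TestTransitions:
    def test_small_example(self):
        # day1 [U, U, R, R] -> day2 [R, U, R, R]
        pairs = [(i, i) for i in range(4)]
        a = ["none", "none", "on", "off"]
        b = ["on", "none", "on", "off"]
        tm = responsiveness_transitions(pairs, a, b)
        assert tm.loc["unresponsive", "responsive"] == 0.5
        assert tm.loc["responsive", "responsive"] == 1.0
        assert np.allclose(tm.sum(axis=1), 1.0)

    def test_identity_classifications(self):
        pairs = [(i, i) for i in range(6)]
        labs = ["on", "off", "none", "none", "reward", "on_off"]
        tm = responsiveness_transitions(pairs, labs, labs)
        assert np.allclose(np.diag(tm), 1.0)

    def test_no_tracked_cells_errors(self):
        with pytest.raises(ValueError):
            responsiveness_transitions([], [], [])

    def test_planted_069_recovered(self):
        rng = np.random.default_rng(8)
        n = 500
        a = np.where(rng.random(n) < 0.5, "none", "on")
        b = a.copy()
        u = a == "none"
        flip = rng.random(n) < 0.69
        b[u & flip] = "on"
        tm = responsiveness_transitions([(i, i) for i in range(n)],
                                        list(a), list(b))
        n_u = int(u.sum())
        se = np.sqrt(0.69 * 0.31 / n_u)
        assert abs(tm.loc["unresponsive", "responsive"] - 0.69) <= 3 * se
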