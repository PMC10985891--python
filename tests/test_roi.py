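"""ROI geometry: selection, merging, cropping and the coordinate round trip."""

import numpy as np
import pytest

from vessel3.phantom import mask_to_instance_boxes
from vessel3.roi import (CropTransform, LabeledBox, NoDetectionsError,
                         NoForegroundError, RoiRect, crop_resize, merge_to_roi,
                         oracle_detector, roi_from_binary_mask,
                         select_best_per_class, uncrop_mask)


def _random_boxes(rng, n, size=256):
    boxes = []
    for _ in range(n):
        x0, y0 = rng.integers(0, size - 10, size=2)
        w, h = rng.integers(2, 30, size=2)
        boxes.append(LabeledBox(int(rng.integers(1, 4)), int(x0), int(y0),
                                int(min(x0 + w, size)), int(min(y0 + h, size)),
                                float(rng.uniform(0, 1))))
    return boxes


class TestSelectBestPerClass:
    def test_highest_confidence_wins(self):
        boxes = [LabeledBox(1, 0, 0, 10, 10, 0.9),
                 LabeledBox(1, 5, 5, 15, 15, 0.6)]
        sel = select_best_per_class(boxes)
        assert sel.boxes == [boxes[0]]
        assert sel.missing_classes == (2, 3)

    def test_empty_input(self):
        sel = select_best_per_class([])
        assert sel.boxes == [] and sel.missing_classes == (1, 2, 3)

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            boxes = _random_boxes(rng, 7)
            sel = select_best_per_class(boxes)
            for k in (1, 2, 3):
                mine = [b for b in sel.boxes if b.class_id == k]
                cand = [b for b in boxes if b.class_id == k]
                if not cand:
                    assert not mine and k in sel.missing_classes
                    continue
                best = max(cand, key=lambda b: (b.confidence, b.area,
                                                -boxes.index(b)))
                assert mine == [best]

    def test_tie_broken_by_area_then_first(self):
        a = LabeledBox(2, 0, 0, 4, 4, 0.7)      # area 16
        b = LabeledBox(2, 0, 0, 8, 8, 0.7)      # area 64, wins
        c = LabeledBox(2, 10, 10, 18, 18, 0.7)  # same area, later: loses
        assert select_best_per_class([a, b, c]).boxes == [b]


class TestMergeToRoi:
    def test_three_box_worked_example(self):
        boxes = [LabeledBox(1, 10, 10, 20, 20), LabeledBox(2, 30, 15, 40, 25),
                 LabeledBox(3, 12, 40, 18, 50)]
        r = merge_to_roi(boxes, margin=5, image_size=(256, 256))
        assert (r.x_min, r.y_min, r.x_max, r.y_max) == (5, 5, 45, 55)

    def test_clamped_at_origin(self):
        r = merge_to_roi([LabeledBox(1, 0, 0, 10, 10)], margin=5,
                         image_size=(256, 256))
        assert (r.x_min, r.y_min, r.x_max, r.y_max) == (0, 0, 15, 15)

    def test_empty_raises_no_detections(self):
        with pytest.raises(NoDetectionsError):
            merge_to_roi([], margin=5, image_size=(256, 256))

    def test_containment_and_tightness(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            boxes = _random_boxes(rng, int(rng.integers(1, 6)))
            r = merge_to_roi(boxes, margin=5, image_size=(256, 256))
            assert all(r.contains_box(b) for b in boxes)
            tight = merge_to_roi(boxes, margin=0, image_size=(256, 256))
            assert tight.x_min == min(b.x_min for b in boxes)
            assert tight.y_min == min(b.y_min for b in boxes)
            assert tight.x_max == max(b.x_max for b in boxes)
            assert tight.y_max == max(b.y_max for b in boxes)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(12)
        boxes = _random_boxes(rng, 5)
        ref = merge_to_roi(boxes, margin=5, image_size=(256, 256))
        for _ in range(10):
            perm = [boxes[i] for i in rng.permutation(5)]
            assert merge_to_roi(perm, margin=5, image_size=(256, 256)) == ref


class TestRoiFromBinaryMask:
    def test_point_dilation(self):
        m = np.zeros((256, 256), bool)
        m[100, 100] = True
        r = roi_from_binary_mask(m, margin=5)
        assert (r.x_min, r.y_min, r.x_max, r.y_max) == (95, 95, 106, 106)

    def test_full_foreground_clamps_to_image(self):
        r = roi_from_binary_mask(np.ones((64, 64), bool), margin=5)
        assert (r.x_min, r.y_min, r.x_max, r.y_max) == (0, 0, 64, 64)

    def test_empty_mask_raises(self):
        with pytest.raises(NoForegroundError):
            roi_from_binary_mask(np.zeros((32, 32), bool), margin=5)

    def test_equivalent_to_box_merge_strategy(self, phantom_batch):
        # strategy 1 (binary mask) == strategy 2 (boxes) at equal margin
        for s in phantom_batch[:10]:
            r1 = roi_from_binary_mask(s.mask > 0, margin=5)
            binary = (s.mask > 0).astype(np.uint8)   # one-class mask
            r2 = merge_to_roi(mask_to_instance_boxes(binary), margin=5,
                              image_size=s.mask.shape)
            assert (r1.x_min, r1.y_min, r1.x_max, r1.y_max) \
                == (r2.x_min, r2.y_min, r2.x_max, r2.y_max)


class TestCropResize:
    def test_identity_roi(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(256, 256))
        out, t = crop_resize(img, RoiRect(0, 0, 256, 256), out_size=(256, 256))
        assert np.array_equal(out, img)
        assert t.scale == (1.0, 1.0)

    def test_scale_factors(self):
        img = np.zeros((256, 256))
        _, t = crop_resize(img, RoiRect(10, 20, 138, 148), out_size=(256, 256))
        assert t.scale == (2.0, 2.0)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            crop_resize(np.zeros((64, 64)), RoiRect(0, 0, 1, 30))

    def test_checkerboard_round_trip_error_bounded(self):
        # down-then-up bilinear resize keeps mean abs error within tolerance
        idx = np.indices((64, 64)) // 8          # 8-px tiles survive 2x down
        tile = idx.sum(0) % 2 * 0.5 + 0.25
        roi = RoiRect(0, 0, 64, 64)
        down, _ = crop_resize(tile, roi, out_size=(32, 32))
        up, _ = crop_resize(down, RoiRect(0, 0, 32, 32), out_size=(64, 64))
        assert np.abs(up - tile).mean() < 0.1


class TestUncropMask:
    def test_identity_transform(self):
        mask = np.random.default_rng(1).integers(0, 4, size=(64, 64)).astype(np.uint8)
        t = CropTransform(RoiRect(0, 0, 64, 64), (64, 64), (64, 64))
        assert np.array_equal(uncrop_mask(mask, t, (64, 64)), mask)

    def test_background_stays_background(self):
        t = CropTransform(RoiRect(10, 10, 42, 42), (32, 32), (64, 64))
        out = uncrop_mask(np.zeros((64, 64), np.uint8), t, (64, 64))
        assert not out.any()

    def test_round_trip_dice_with_integer_scale(self, phantom_batch):
        from vessel3.metrics import confusion, dice_score
        for s in phantom_batch[:5]:
            roi = roi_from_binary_mask(s.mask > 0, margin=6)
            # pad ROI to even size for an exact 2x scale
            h, w = roi.shape
            roi = RoiRect(roi.x_min, roi.y_min,
                          roi.x_max + w % 2, roi.y_max + h % 2)
            h, w = roi.shape
            crop = s.mask[roi.y_min:roi.y_max, roi.x_min:roi.x_max]
            up = np.kron(crop, np.ones((2, 2), dtype=np.uint8))  # exact 2x
            t = CropTransform(roi, (h, w), (2 * h, 2 * w))
            back = uncrop_mask(up, t, s.mask.shape)
            for k in (1, 2, 3):
                assert dice_score(confusion(back, s.mask, k)) >= 90.0

    def test_size_mismatch_rejected(self):
        t = CropTransform(RoiRect(0, 0, 32, 32), (32, 32), (64, 64))
        with pytest.raises(ValueError):
            uncrop_mask(np.zeros((32, 32), np.uint8), t, (64, 64))


class TestOracleDetector:
    def test_identity_when_exact(self, phantom_batch):
        boxes = phantom_batch[0].boxes
        assert oracle_detector(boxes, jitter_px=0, drop_prob=0.0, seed=1) == boxes

    def test_drop_all(self, phantom_batch):
        assert oracle_detector(phantom_batch[0].boxes, drop_prob=1.0, seed=1) == []

    def test_jitter_bounded(self):
        gt = [LabeledBox(1, 50, 60, 90, 100), LabeledBox(3, 120, 130, 131, 141)]
        for seed in range(1000):
            for b, o in zip(gt, oracle_detector(gt, jitter_px=3, seed=seed,
                                                image_size=(256, 256))):
                assert abs(o.x_min - b.x_min) <= 3 and abs(o.y_min - b.y_min) <= 3
                assert abs(o.x_max - b.x_max) <= 3 and abs(o.y_max - b.y_max) <= 3
                assert 0.5 <= o.confidence <= 1.0
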