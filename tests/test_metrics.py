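"""Evaluation metrics vs brute-force oracles and algebraic identities."""

import numpy as np
import pytest

from vessel3.metrics import (ConfusionCounts, UndefinedMetricError, confusion,
                             dice_score, evaluate_batch, extract_boundary,
                             hausdorff, hausdorff_masks, iou, read_report,
                             write_report)


def _brute_hausdorff(a, b):
    """All-pairs double loop (the defining formula)."""
    def directed(p, q):
        return max(min(np.hypot(x1 - x2, y1 - y2) for x2, y2 in q)
                   for x1, y1 in p)
    return max(directed(a, b), directed(b, a))


def _random_mask_pair(rng, size):
    p = np.zeros((size, size), dtype=np.uint8)
    g = np.zeros((size, size), dtype=np.uint8)
    for m in (p, g):
        for k in (1, 2, 3):
            r, c = rng.integers(2, size - 2, size=2)
            rad = int(rng.integers(1, 4))
            yy, xx = np.ogrid[:size, :size]
            m[(yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2] = k
    return p, g


class TestConfusion:
    def test_hand_counted_toy(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        pr = np.zeros((4, 4), dtype=np.uint8)
        gt[0, 0] = gt[0, 1] = gt[0, 2] = 1       # 3 positives
        pr[0, 0] = pr[0, 1] = pr[1, 0] = 1       # 2 overlap, 1 extra, 1 missed
        c = confusion(pr, gt, 1)
        assert (c.tp, c.fp, c.fn) == (2, 1, 1)

    def test_counts_partition_the_image(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p, g = _random_mask_pair(rng, 16)
            for k in (1, 2, 3):
                assert confusion(p, g, k).total == 256

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((4, 4)), np.zeros((4, 5)), 1)


class TestOverlapScores:
    def test_substitution_values(self):
        c = ConfusionCounts(tp=2, fp=1, fn=1, tn=12)
        assert iou(c) == pytest.approx(50.0)
        assert dice_score(c) == pytest.approx(66.67, abs=0.01)

    def test_perfect_match(self):
        c = ConfusionCounts(tp=9, fp=0, fn=0, tn=7)
        assert iou(c) == 100.0 and dice_score(c) == 100.0

    def test_disjoint_masks_score_zero(self):
        c = ConfusionCounts(tp=0, fp=4, fn=4, tn=8)
        assert dice_score(c) == 0.0

    def test_undefined_when_absent_in_both(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=16)
        with pytest.raises(UndefinedMetricError):
            iou(c)
        with pytest.raises(UndefinedMetricError):
            dice_score(c)

    def test_dice_iou_identity_and_ordering(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p, g = _random_mask_pair(rng, 16)
            for k in (1, 2, 3):
                c = confusion(p, g, k)
                try:
                    i, d = iou(c) / 100, dice_score(c) / 100
                except UndefinedMetricError:
                    continue
                assert d == pytest.approx(2 * i / (1 + i), abs=1e-9)
                assert i <= d + 1e-12


class TestBoundary:
    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        np.testing.assert_array_equal(extract_boundary(m), [[2, 3]])

    def test_filled_square_perimeter(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        b = {tuple(p) for p in extract_boundary(m)}
        assert (2, 2) not in b
        assert len(b) == 8

    def test_boundary_subset_of_mask(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = rng.uniform(size=(12, 12)) < 0.4
            if not m.any():
                continue
            for r, c in extract_boundary(m):
                assert m[r, c]

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedMetricError):
            extract_boundary(np.zeros((4, 4), bool))


class TestHausdorff:
    def test_identical_sets(self):
        a = np.array([[0, 0], [3, 1]])
        assert hausdorff(a, a) == 0.0

    def test_pythagorean_pair(self):
        assert hausdorff(np.array([[0, 0]]), np.array([[3, 4]])) == 5.0

    def test_directed_asymmetry_resolved_by_max(self):
        a = np.array([[0, 0], [10, 0]])
        b = np.array([[0, 0]])
        assert hausdorff(a, b) == 10.0

    def test_symmetry_and_translation_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 20, size=(6, 2))
            b = rng.integers(0, 20, size=(4, 2))
            assert hausdorff(a, b) == hausdorff(b, a)
            t = rng.integers(-3, 4, size=2)
            shift = np.linalg.norm(t)
            assert abs(hausdorff(a, b + t) - hausdorff(a, b)) <= shift + 1e-9

    def test_matches_brute_force_on_masks(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p, g = _random_mask_pair(rng, 16)
            pb, gb = p == 1, g == 1
            if not (pb.any() and gb.any()):
                continue
            expect = _brute_hausdorff(extract_boundary(pb).tolist(),
                                      extract_boundary(gb).tolist())
            assert hausdorff_masks(pb, gb) == pytest.approx(expect, abs=1e-9)


class TestEvaluateBatch:
    def test_perfect_predictions(self, phantom_batch):
        masks = [s.mask for s in phantom_batch[:5]]
        rep = evaluate_batch(masks, masks)
        for name in ("PA", "Ao", "SVC"):
            assert rep.per_class[name]["dice"] == 100.0
            assert rep.per_class[name]["iou"] == 100.0
            assert rep.per_class[name]["hd"] == 0.0
        assert rep.mean["dice"] == 100.0

    def test_mean_is_arithmetic_over_classes(self, phantom_batch):
        preds = [s.mask for s in phantom_batch[:4]]
        gts = [np.roll(m, 2, axis=0) for m in preds]
        rep = evaluate_batch(preds, gts)
        for key in ("dice", "iou", "hd"):
            expect = np.mean([rep.per_class[n][key] for n in ("PA", "Ao", "SVC")])
            assert rep.mean[key] == pytest.approx(expect, abs=1e-9)

    def test_matches_scripted_per_image_loop(self, phantom_batch):
        preds = [np.roll(s.mask, 1, axis=1) for s in phantom_batch[:4]]
        gts = [s.mask for s in phantom_batch[:4]]
        rep = evaluate_batch(preds, gts)
        for k, name in ((1, "PA"), (3, "SVC")):
            dices = [dice_score(confusion(p, g, k)) for p, g in zip(preds, gts)]
            hds = [hausdorff_masks(p == k, g == k) for p, g in zip(preds, gts)]
            assert rep.per_class[name]["dice"] == pytest.approx(np.mean(dices))
            assert rep.per_class[name]["hd"] == pytest.approx(np.mean(hds))

    def test_absent_class_skipped_not_inflated(self):
        pred = np.zeros((8, 8), dtype=np.uint8)
        gt = np.zeros((8, 8), dtype=np.uint8)
        pred[0, 0] = gt[0, 1] = 1                # class 1 present, 2/3 absent
        rep = evaluate_batch([pred], [gt])
        assert rep.per_class["Ao"]["n_overlap"] == 0
        assert np.isnan(rep.per_class["Ao"]["dice"])
        assert rep.per_class["PA"]["n_overlap"] == 1

    def test_report_round_trip_and_csv_layout(self, tmp_path, phantom_batch):
        masks = [s.mask for s in phantom_batch[:3]]
        rep = evaluate_batch(masks, masks)
        csv_path, json_path = write_report(rep, tmp_path / "report")
        again = read_report(json_path)
        assert again.to_dict() == rep.to_dict()
        lines = open(csv_path).read().strip().splitlines()
        assert lines[0].split(",") == ["Class", "Dice", "IoU", "HD"]
        assert [ln.split(",")[0] for ln in lines[1:]] == ["PA", "Ao", "SVC", "Mean"]
        assert lines[1].split(",")[1] == "100.00"
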