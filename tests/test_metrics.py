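import numpy as np
import pytest

import oracles
from liverseg.metrics import (
    dice,
    dice_global,
    dice_per_case,
    evaluate_cases,
    hausdorff,
    lesion_recall_at_overlap,
    pixel_recall,
)


def random_mask(rng, shape, p):
    return rng.random(shape) < p


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = random_mask(rng, (5, 5, 5), 0.4)
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_value(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, :4, 0] = True  # |a| = 4
        b[0, 2:, 0] = True
        b[1, :2, 0] = True  # |b| = 4, overlap = 2
        assert dice(a, b) == 0.5

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3, 3), bool)
        assert dice(empty, empty) == 1.0

    def test_symmetric(self, rng):
        a, b = random_mask(rng, (6, 6, 6), 0.3), random_mask(rng, (6, 6, 6), 0.3)
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestAggregation:
    def test_per_case_mean_and_sd(self, rng):
        a = random_mask(rng, (4, 4, 4), 0.5)
        cases = [(a, a), (a, ~a & a)]  # dice 1.0 and 0.0... second is (a, empty)
        cases = [(a, a), (np.zeros_like(a), a)]  # dice 1.0, 0.0
        mean, sd = dice_per_case(cases)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.std([1.0, 0.0], ddof=1))

    def test_single_case_sd_zero(self, rng):
        a = random_mask(rng, (4, 4, 4), 0.5)
        mean, sd = dice_per_case([(a, a)])
        assert (mean, sd) == (1.0, 0.0)

    def test_global_pools_voxel_counts(self):
        a1 = np.zeros((10, 1, 1), bool); a1[:10] = True
        t1 = a1.copy()                      # 10/10 overlap
        a2 = np.zeros((10, 1, 1), bool); a2[:5] = True
        t2 = np.zeros((10, 1, 1), bool); t2[5:] = True  # disjoint, 5+5
        pooled = dice_global([(a1, t1), (a2, t2)])
        assert pooled == pytest.approx(2 * 10 / (20 + 10))
        # and pooled Dice lies between the per-case extremes
        assert 0.0 < pooled < 1.0

    def test_global_equals_case_dice_for_single_case(self, rng):
        a, b = random_mask(rng, (5, 5, 5), 0.4), random_mask(rng, (5, 5, 5), 0.4)
        assert dice_global([(a, b)]) == pytest.approx(dice(a, b))

    def test_global_matches_brute_force_on_random_cases(self, rng):
        cases = [
            (random_mask(rng, (6, 6, 6), 0.3), random_mask(rng, (6, 6, 6), 0.3))
            for _ in range(5)
        ]
        assert dice_global(cases) == pytest.approx(oracles.brute_dice_global(cases))


class TestHausdorff:
    def test_identical_masks_distance_zero(self, rng):
        m = random_mask(rng, (5, 5, 5), 0.4)
        m[2, 2, 2] = True
        assert hausdorff(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((6, 6, 2), bool)
        b = np.zeros((6, 6, 2), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_anisotropic_spacing_scales_distance(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[0, 0, 2] = True
        assert hausdorff(a, b, spacing=(1.0, 1.0, 5.0)) == pytest.approx(10.0)

    def test_cube_and_dilation_distance_one(self):
        from scipy import ndimage

        a = np.zeros((8, 8, 8), bool)
        a[2:6, 2:6, 2:6] = True
        b = ndimage.binary_dilation(a, ndimage.generate_binary_structure(3, 1))
        assert hausdorff(a, b) == pytest.approx(
            oracles.brute_hausdorff(a, b), abs=1e-9
        )

    def test_empty_mask_rejected(self, rng):
        m = random_mask(rng, (4, 4, 4), 0.5)
        m[0, 0, 0] = True
        with pytest.raises(ValueError, match="empty"):
            hausdorff(m, np.zeros((4, 4, 4), bool))


class TestPixelRecall:
    def test_superset_prediction(self, rng):
        t = random_mask(rng, (5, 5, 5), 0.3)
        t[1, 1, 1] = True
        assert pixel_recall(np.ones_like(t), t) == 1.0

    def test_disjoint_prediction(self):
        t = np.zeros((4, 4, 4), bool); t[0, 0, 0] = True
        p = np.zeros((4, 4, 4), bool); p[3, 3, 3] = True
        assert pixel_recall(p, t) == 0.0

    def test_half_covered(self):
        t = np.zeros((4, 1, 1), bool); t[:4] = True
        p = np.zeros((4, 1, 1), bool); p[:2] = True
        assert pixel_recall(p, t) == 0.5

    def test_empty_truth_rejected(self, rng):
        with pytest.raises(ValueError, match="undefined"):
            pixel_recall(random_mask(rng, (3, 3, 3), 0.5), np.zeros((3, 3, 3), bool))


class TestLesionRecall:
    def _two_lesions(self):
        t = np.zeros((10, 10, 4), bool)
        t[1:3, 1:3, 1:3] = True
        t[7:9, 7:9, 1:3] = True
        return t

    def test_perfect_prediction(self):
        t = self._two_lesions()
        assert lesion_recall_at_overlap(t, t) == 1.0

    def test_one_lesion_missed(self):
        t = self._two_lesions()
        p = t.copy()
        p[7:9, 7:9, :] = False
        assert lesion_recall_at_overlap(p, t) == 0.5

    def test_threshold_semantics_iou_below_cutoff(self):
        t = np.zeros((8, 8, 2), bool)
        t[0:5, 0, 0] = True  # lesion of 5 voxels
        p = np.zeros((8, 8, 2), bool)
        p[0:2, 0, 0] = True  # overlap 2, union 5 -> IoU 0.4
        assert lesion_recall_at_overlap(p, t, threshold=0.5) == 0.0
        assert lesion_recall_at_overlap(p, t, threshold=0.4) == 1.0

    def test_no_truth_lesions_flagged_undefined(self):
        assert lesion_recall_at_overlap(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool)) is None

    def test_monotone_nonincreasing_in_threshold(self, rng):
        for _ in range(10):
            p = random_mask(rng, (8, 8, 8), 0.2)
            t = random_mask(rng, (8, 8, 8), 0.2)
            if not t.any():
                continue
            values = [lesion_recall_at_overlap(p, t, threshold=th) for th in (0.1, 0.3, 0.5, 0.7, 0.9)]
            assert all(a >= b for a, b in zip(values, values[1:]))


class TestEvaluateCases:
    def _volumes(self, rng, n=3):
        out = {}
        for i in range(n):
            labels = np.zeros((12, 12, 6), dtype=np.int16)
            labels[3:9, 3:9, 1:5] = 1
            labels[5:7, 5:7, 2:4] = 2
            out[f"case{i}"] = labels
        return out

    def test_perfect_predictions_give_unit_scores(self, rng):
        truths = self._volumes(rng)
        report = evaluate_cases(dict(truths), truths)
        assert report.summary["dice_per_case_liver"] == 1.0
        assert report.summary["dice_per_case_tumor"] == 1.0
        assert report.summary["hausdorff_liver_mean"] == 0.0
        assert report.summary["recall_at_50_overlap"] == 1.0

    def test_missing_case_error_names_id(self, rng):
        truths = self._volumes(rng)
        preds = dict(truths)
        del preds["case1"]
        with pytest.raises(ValueError, match="case1"):
            evaluate_cases(preds, truths)

    def test_report_deterministic(self, rng):
        truths = self._volumes(rng)
        preds = {k: np.where(np.random.default_rng(1).random(v.shape) < 0.9, v, 0).astype(np.int16)
                 for k, v in truths.items()}
        r1 = evaluate_cases(preds, truths)
        r2 = evaluate_cases(preds, truths)
        assert r1.per_case.equals(r2.per_case)
        assert r1.summary == r2.summary

    def test_shape_mismatch_error_names_case(self, rng):
        truths = self._volumes(rng)
        preds = dict(truths)
        preds["case2"] = np.zeros((4, 4, 4), dtype=np.int16)
        with pytest.raises(ValueError, match="case2"):
            evaluate_cases(preds, truths)
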