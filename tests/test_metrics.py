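"""Morphometrics, NCR and segmentation evaluation (incl. brute-force oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmseg import (DataError, DegenerateInputError, ShapeMismatchError,
                    compute_ncr, evaluate, f_measure, morphometrics,
                    sensitivity_map)


def brute_force_confusion(pred, gold, fov_area):
    """Independent per-object / per-pixel double-loop confusion counts."""
    object_tp = object_fn = object_fp = 0
    for g in np.unique(gold[gold > 0]):
        hit = False
        for r, c in zip(*np.nonzero(gold == g)):
            if pred[r, c] > 0:
                hit = True
                break
        object_tp += hit
        object_fn += not hit
    for p in np.unique(pred[pred > 0]):
        overlap = False
        for r, c in zip(*np.nonzero(pred == p)):
            if gold[r, c] > 0:
                overlap = True
                break
        object_fp += not overlap
    tp = fp = fn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, g = pred[r, c] > 0, gold[r, c] > 0
            tp += p and g
            fp += p and not g
            fn += g and not p
    tn = fov_area - tp - fp - fn
    return object_tp, object_fn, object_fp, tp, fp, fn, tn


def random_label_pair(rng, shape=(32, 32)):
    from skimage.measure import label as cc_label
    pred = cc_label(rng.random(shape) < 0.2, connectivity=2)
    gold = cc_label(rng.random(shape) < 0.2, connectivity=2)
    return pred, gold


class TestNcr:
    def test_half_fov_gives_unity(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[:5] = 1
        assert compute_ncr(mask, 100) == pytest.approx(1.0)

    def test_empty_mask_gives_zero(self):
        assert compute_ncr(np.zeros((5, 5), dtype=np.int32), 25) == 0.0

    def test_direct_arithmetic(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask.ravel()[:100] = 1
        assert compute_ncr(mask, 1100) == pytest.approx(0.1)

    def test_objects_filling_fov_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_ncr(np.ones((5, 5), dtype=np.int32), 25)


class TestMorphometrics:
    def test_physical_units_of_nominal_nucleus(self):
        # 90 px^2 at 0.75 um/px: 50.625 um^2, equivalent diameter 8.03 um.
        mask = np.zeros((20, 20), dtype=np.int32)
        mask.ravel()[:90] = 1
        report = morphometrics(mask, pixel_scale=0.75)
        assert report.mean_area == pytest.approx(50.625)
        assert report.mean_diameter == pytest.approx(8.03, abs=0.005)
        assert report.mean_diameter == pytest.approx(
            2 * np.sqrt(report.mean_area / np.pi))

    def test_equal_objects_have_zero_std(self):
        mask = np.zeros((30, 30), dtype=np.int32)
        mask[0:10, 0:10] = 1
        mask[15:25, 15:25] = 2
        report = morphometrics(mask, pixel_scale=0.5)
        assert report.n_objects == 2
        assert report.mean_area == pytest.approx(100 * 0.25)
        assert report.area_std == 0.0

    def test_object_count_matches_distinct_labels(self, rng):
        mask = np.zeros((30, 30), dtype=np.int32)
        mask[1:4, 1:4] = 4
        mask[10:12, 10:15] = 9
        assert morphometrics(mask).n_objects == 2

    def test_empty_mask_gives_zero_report(self):
        report = morphometrics(np.zeros((5, 5), dtype=np.int32))
        assert report.n_objects == 0
        assert report.mean_area == 0.0 and report.ncr == 0.0


class TestFMeasure:
    def test_perfect_scores(self):
        assert f_measure(1.0, 1.0) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert f_measure(0.5, 1.0) == pytest.approx(2 / 3, abs=5e-5)

    def test_zero_sensitivity_gives_zero(self):
        assert f_measure(0.0, 0.9) == 0.0

    def test_undefined_at_origin(self):
        with pytest.raises(DegenerateInputError):
            f_measure(0.0, 0.0)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_symmetric_and_bounded(self, s, p):
        f = f_measure(s, p)
        assert f == pytest.approx(f_measure(p, s))
        assert min(s, p) <= f + 1e-12
        assert f <= max(s, p) + 1e-12


class TestEvaluate:
    def test_identical_masks_are_perfect(self, rng):
        pred, gold = random_label_pair(rng)
        rep = evaluate(pred, pred, pred.size)
        assert rep.object_sensitivity == 1.0
        assert rep.pixel_sensitivity == 1.0
        assert rep.pixel_specificity == 1.0
        assert rep.f_measure == 1.0

    def test_empty_prediction(self, rng):
        _, gold = random_label_pair(rng)
        rep = evaluate(np.zeros_like(gold), gold, gold.size)
        assert rep.object_sensitivity == 0.0
        assert rep.pixel_specificity == 1.0

    def test_hand_counted_any_pixel_rule(self):
        # Gold: one 10-px object. Pred: one object covering exactly 1 gold
        # pixel plus 4 pixels outside.
        gold = np.zeros((8, 8), dtype=np.int32)
        gold[2, 0:10 // 2] = 1
        gold[3, 0:5] = 1
        pred = np.zeros((8, 8), dtype=np.int32)
        pred[3, 4] = 1          # the single overlapping pixel
        pred[4, 4:8] = 1        # 4 pixels outside the gold object
        rep = evaluate(pred, gold, 64)
        assert rep.object_tp == 1 and rep.object_fn == 0
        assert rep.pixel_tp == 1 and rep.pixel_fp == 4
        assert rep.pixel_sensitivity == pytest.approx(0.1)

    def test_shared_prediction_credits_both_gold_objects(self):
        gold = np.zeros((6, 6), dtype=np.int32)
        gold[1, 1] = 1
        gold[1, 4] = 2
        pred = np.zeros((6, 6), dtype=np.int32)
        pred[1, 1:5] = 1  # spans both gold objects
        rep = evaluate(pred, gold, 36)
        assert rep.object_tp == 2
        assert rep.object_fp == 0

    def test_confusion_counts_partition_fov(self, rng):
        pred, gold = random_label_pair(rng)
        rep = evaluate(pred, gold, 2000)
        assert (rep.pixel_tp + rep.pixel_fp + rep.pixel_fn
                + rep.pixel_tn) == 2000
        n_gold = np.unique(gold[gold > 0]).size
        assert rep.object_tp + rep.object_fn == n_gold

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            pred, gold = random_label_pair(rng)
            rep = evaluate(pred, gold, pred.size)
            assert (rep.object_tp, rep.object_fn, rep.object_fp,
                    rep.pixel_tp, rep.pixel_fp, rep.pixel_fn,
                    rep.pixel_tn) == brute_force_confusion(
                        pred, gold, pred.size)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            evaluate(np.zeros((4, 4), dtype=int),
                     np.zeros((5, 5), dtype=int), 25)

    def test_small_fov_rejected(self):
        pred = np.ones((4, 4), dtype=np.int32)
        gold = np.zeros((4, 4), dtype=np.int32)
        with pytest.raises(DataError):
            evaluate(pred, gold, 10)


class TestSensitivityMap:
    GREEN, BLUE, RED = (0, 255, 0), (0, 0, 255), (255, 0, 0)

    def test_identical_masks_have_no_errors(self, rng):
        pred, _ = random_label_pair(rng)
        rgb = sensitivity_map(pred, pred)
        assert not (np.all(rgb == self.RED, axis=-1)).any()
        assert not (np.all(rgb == self.BLUE, axis=-1)).any()

    def test_missed_gold_shows_blue(self, rng):
        _, gold = random_label_pair(rng)
        rgb = sensitivity_map(np.zeros_like(gold), gold)
        n_blue = int(np.all(rgb == self.BLUE, axis=-1).sum())
        assert n_blue == int((gold > 0).sum())

    def test_hand_counted_fixture_colors(self):
        gold = np.zeros((8, 8), dtype=np.int32)
        gold[2, 0:5] = 1
        gold[3, 0:5] = 1
        pred = np.zeros((8, 8), dtype=np.int32)
        pred[3, 4] = 1
        pred[4, 4:8] = 1
        rgb = sensitivity_map(pred, gold)
        assert int(np.all(rgb == self.GREEN, axis=-1).sum()) == 1
        assert int(np.all(rgb == self.BLUE, axis=-1).sum()) == 9
        assert int(np.all(rgb == self.RED, axis=-1).sum()) == 4
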