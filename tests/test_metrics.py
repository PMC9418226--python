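"""Metric formulas against independent oracles, and the comparison statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fafseg.metrics import (
    ci95,
    compute_metrics,
    confusion_counts,
    evaluate_pair,
    mann_whitney,
    percent_difference,
    summarize_metrics,
)

from conftest import make_random_mask_pair


def brute_force_metrics(pred, gt):
    """Independent per-pixel loop oracle for all five metrics."""
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = int(pred[i, j]), int(gt[i, j])
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
    out = {"accuracy": (tp + tn) / (tp + fp + tn + fn)}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["dice"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    out["iou"] = tp / (tp + fp + fn) if tp + fp + fn else None
    return out


class TestConfusionCounts:
    def test_perfect_prediction(self):
        m = np.ones((10, 10), dtype=np.uint8)
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.tn, c.fn) == (100, 0, 0, 0)

    def test_complement_has_no_agreement(self, rng):
        gt = (rng.random((12, 12)) < 0.5).astype(np.uint8)
        c = confusion_counts(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0
        assert c.fp + c.fn == gt.size

    def test_hand_placed_4x4_fixture(self):
        # 3 TP, 2 FP, 1 FN, 10 TN laid out by hand
        gt = np.array(
            [[1, 1, 0, 0],
             [1, 1, 0, 0],
             [0, 0, 0, 0],
             [0, 0, 0, 0]], dtype=np.uint8)
        pred = np.array(
            [[1, 1, 0, 0],
             [1, 0, 1, 0],
             [0, 1, 0, 0],
             [0, 0, 0, 0]], dtype=np.uint8)
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 1, 10)
        m = compute_metrics(c)
        assert m.dice == pytest.approx(6 / 9)
        assert m.iou == pytest.approx(0.5)
        assert m.accuracy == pytest.approx(13 / 16)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.array([[0, 2]]), np.array([[0, 1]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int))


class TestMetricFormulas:
    def test_agrees_with_pixel_loop_oracle(self, rng):
        for _ in range(200):
            pred, gt = make_random_mask_pair(rng)
            ours = evaluate_pair(pred, gt)
            ref = brute_force_metrics(pred, gt)
            for name, val in ref.items():
                if val is not None:
                    assert getattr(ours, name) == pytest.approx(val, abs=1e-12)

    def test_dice_iou_identity(self, rng):
        for _ in range(300):
            pred, gt = make_random_mask_pair(rng, shape=(12, 12))
            m = evaluate_pair(pred, gt)
            if not math.isnan(m.dice):
                assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-12)

    def test_both_masks_empty_convention(self):
        z = np.zeros((8, 8), dtype=np.uint8)
        m = evaluate_pair(z, z)
        assert m.dice == 1.0 and m.iou == 1.0 and m.sensitivity == 1.0
        assert m.specificity == 1.0 and m.accuracy == 1.0
        assert {"dice", "iou", "sensitivity"} <= set(m.undefined)

    def test_empty_reference_nonempty_prediction(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        pred = np.zeros((4, 4), dtype=np.uint8)
        pred[0, 0] = 1
        m = evaluate_pair(pred, gt)
        assert m.dice == 0.0 and math.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined


class TestPercentDifference:
    def test_equal_inputs_give_zero(self):
        assert percent_difference(0.37, 0.37) == 0.0

    @pytest.mark.parametrize(
        "m1, m2, printed_pct, digits",
        [
            (0.66, 0.77, 17.0, 0),    # IoU improvement
            (0.96, 0.98, 2.1, 1),     # accuracy improvement
            (0.64, 0.68, 6.0, 0),     # 12-month IoU disease gap
        ],
    )
    def test_worked_examples_at_printed_precision(self, m1, m2, printed_pct, digits):
        assert round(100 * percent_difference(m1, m2), digits) == printed_pct

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 0.5)


def enumerate_mann_whitney(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), bool)
        sel[list(combo)] = True
        aa, bb = pooled[sel], pooled[~sel]
        us.append(
            sum(1 for x in aa for y in bb if x > y)
            + 0.5 * sum(1 for x in aa for y in bb if x == y)
        )
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value >= 0.9

    def test_fully_separated_triples(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)  # 2/20 enumerated

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_u_statistics_sum_identity(self, seed):
        g = np.random.default_rng(seed)
        n_a, n_b = int(g.integers(1, 8)), int(g.integers(1, 8))
        a, b = g.random(n_a), g.random(n_b)
        ua = mann_whitney(a, b).u
        ub = mann_whitney(b, a).u
        assert ua + ub == pytest.approx(n_a * n_b)

    def test_exact_path_matches_enumeration_small_samples(self):
        g = np.random.default_rng(0)
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                a = g.permutation(np.arange(1, n_a + n_b + 1))[:n_a].astype(float)
                b = np.setdiff1d(np.arange(1, n_a + n_b + 1), a).astype(float)
                r = mann_whitney(a, b)
                u_ref, p_ref = enumerate_mann_whitney(a, b)
                assert r.method == "exact"
                assert r.u == pytest.approx(u_ref)
                assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestCI95:
    def test_constant_sample_has_zero_halfwidth(self):
        mean, hw = ci95([0.5] * 6)
        assert mean == 0.5 and hw == 0.0

    def test_two_point_closed_form(self):
        mean, hw = ci95([0.0, 1.0])
        assert mean == 0.5
        assert hw == pytest.approx(1.959964 * np.std([0, 1], ddof=1) / np.sqrt(2))
        assert hw == pytest.approx(0.98, abs=0.005)

    def test_scaling_linearity(self, rng):
        vals = rng.random(10)
        _, hw = ci95(vals)
        _, hw3 = ci95(3.0 * vals)
        assert hw3 == pytest.approx(3.0 * hw)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ci95([1.0])


def test_summary_aggregation_orders_differ_on_unbalanced_folds():
    import pandas as pd

    df = pd.DataFrame(
        {
            "fold": [0, 0, 0, 1],
            "accuracy": [0.9, 0.9, 0.9, 0.5],
            "sensitivity": [1, 1, 1, 1],
            "specificity": [1, 1, 1, 1],
            "dice": [1, 1, 1, 1],
            "iou": [1, 1, 1, 1.0],
        }
    )
    by_folds = summarize_metrics(df, order="images_then_folds")
    pooled = summarize_metrics(df, order="pooled")
    acc_f = by_folds.set_index("metric").loc["accuracy", "mean"]
    acc_p = pooled.set_index("metric").loc["accuracy", "mean"]
    assert acc_f == pytest.approx(0.7)
    assert acc_p == pytest.approx(0.8)
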