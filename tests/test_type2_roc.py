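import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emometa.type2_roc import (
    DEFAULT_GRID,
    UndefinedCurveWarning,
    auroc2,
    confusion_at_criterion,
    roc_points,
)


def pairwise_auroc2(correct, conf, grid=DEFAULT_GRID):
    """Independent oracle: tie-corrected pairwise enumeration on grid bins.

    AUROC2 equals the probability that a random correct trial's grid-binned
    confidence exceeds a random incorrect trial's, ties counting 1/2.
    """
    grid = np.asarray(grid)
    bins = [int(np.sum(c >= grid)) for c in conf]
    wins = Fraction(0)
    pos = [b for b, ok in zip(bins, correct) if ok]
    neg = [b for b, ok in zip(bins, correct) if not ok]
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                wins += Fraction(1, 2)
    return Fraction(wins, len(pos) * len(neg))


class TestConfusion:
    def test_hand_counted_example(self):
        c = confusion_at_criterion(([True, True, False, False], [80, 60, 60, 20]), 65)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 2)

    def test_criterion_one_everything_high(self):
        c = confusion_at_criterion(([True, False, True], [1, 50, 100]), 1)
        assert c.fn == 0 and c.tn == 0

    def test_all_correct_no_negatives(self):
        c = confusion_at_criterion(([True, True], [30, 70]), 50)
        assert c.fp == 0 and c.tn == 0

    def test_totals_preserved_at_every_criterion(self):
        correct = [True, False, True, False, True]
        conf = [10, 35, 60, 85, 100]
        for x in DEFAULT_GRID:
            c = confusion_at_criterion((correct, conf), x)
            assert c.tp + c.fp + c.tn + c.fn == 5


class TestRocPoints:
    def test_perfect_separation_hits_corner(self):
        curve = roc_points(([True, True, False, False], [100, 100, 1, 1]))
        assert (0.0, 1.0) in curve.points

    def test_constant_confidence_step_curve(self):
        curve = roc_points(([True, False] * 4, [50] * 8))
        for c, (fpr, tpr) in zip(curve.confusions, curve.points):
            expected = (1.0, 1.0) if c.criterion <= 50 else (0.0, 0.0)
            assert (fpr, tpr) == expected

    def test_hand_enumerated_point_set(self):
        curve = roc_points(([True, True, False, False], [80, 60, 60, 20]))
        assert set(curve.points) == {(1.0, 1.0), (0.5, 1.0), (0.0, 0.5), (0.0, 0.0)}

    def test_rates_non_increasing_in_criterion(self):
        rng = np.random.default_rng(5)
        correct = rng.random(60) < 0.5
        conf = rng.integers(1, 101, 60)
        curve = roc_points((correct, conf))
        pts = np.array(curve.points)
        assert np.all(np.diff(pts[:, 0]) <= 0) and np.all(np.diff(pts[:, 1]) <= 0)

    def test_single_class_curve_undefined(self):
        curve = roc_points(([True, True, True], [10, 50, 90]))
        assert not curve.defined
        with pytest.warns(UndefinedCurveWarning):
            assert math.isnan(auroc2(curve))


class TestAuroc2:
    def test_worked_micro_example(self):
        curve = roc_points(([True, True, False, False], [80, 60, 60, 20]))
        assert auroc2(curve) == pytest.approx(0.875, abs=1e-12)

    def test_perfect_separation_is_one(self):
        curve = roc_points(([True] * 5 + [False] * 5, [90] * 5 + [10] * 5))
        assert auroc2(curve) == pytest.approx(1.0)

    def test_independent_confidence_is_chance(self):
        rng = np.random.default_rng(99)
        correct = rng.random(20_000) < 0.5
        conf = rng.integers(1, 101, 20_000)
        curve = roc_points((correct, conf))
        assert auroc2(curve) == pytest.approx(0.5, abs=0.02)

    def test_label_swap_reflects_area(self):
        rng = np.random.default_rng(7)
        correct = rng.random(50) < 0.5
        conf = rng.integers(1, 101, 50)
        a = auroc2(roc_points((correct, conf)))
        b = auroc2(roc_points((~correct, conf)))
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_monotone_confidence_transform_invariance(self):
        # squeeze confidences within their 5-wide grid bins: area unchanged
        rng = np.random.default_rng(13)
        correct = rng.random(40) < 0.5
        conf = rng.integers(1, 101, 40)
        within_bin = 5 * (conf // 5) + np.maximum(1, conf % 5)  # same bin, different value
        same_bin = (conf // 5) == (within_bin // 5)
        conf2 = np.where(same_bin, within_bin, conf)
        a = auroc2(roc_points((correct, conf)))
        b = auroc2(roc_points((correct, conf2)))
        assert a == pytest.approx(b, abs=1e-12)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_pairwise_enumeration_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=20))
        correct = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda c: any(c) and not all(c)
            )
        )
        conf = data.draw(
            st.lists(st.integers(min_value=1, max_value=100), min_size=n, max_size=n)
        )
        area = auroc2(roc_points((correct, conf)))
        oracle = pairwise_auroc2(correct, conf)
        assert area == pytest.approx(float(oracle), abs=1e-12)
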