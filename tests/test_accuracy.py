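"""Accuracy machinery: 2x2 tables, odds ratios, ROC and cubic trends."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from ogtt_screen.accuracy import (
    ConfusionTable,
    accuracy_point,
    confusion,
    cubic_trend,
    odds_ratio,
    roc_auc,
)


def test_confusion_identity_and_hand_enumeration():
    same = [True, True, False, False]
    t = confusion(same, same)
    assert (t.fp, t.fn) == (0, 0)
    # 10 subjects, predicted {1..5}, reference {4..8}
    pred = [i in range(1, 6) for i in range(1, 11)]
    ref = [i in range(4, 9) for i in range(1, 11)]
    t = confusion(pred, ref)
    assert (t.tp, t.fp, t.fn, t.tn) == (2, 3, 3, 2)


def test_confusion_drops_missing_pairs_and_requires_some():
    t = confusion([True, None, False], [True, True, np.nan])
    assert t.total == 1 and t.tp == 1
    with pytest.raises(ValueError):
        confusion([None], [True])


def test_accuracy_point_hand_values():
    p = accuracy_point(ConfusionTable(tp=8, fp=2, fn=2, tn=88))
    assert p.sensitivity == pytest.approx(0.8)
    assert p.specificity == pytest.approx(88 / 90)
    assert p.ppv == pytest.approx(0.8)
    assert p.npv == pytest.approx(88 / 90)
    assert p.positives_fraction == pytest.approx(0.1)


def test_accuracy_point_undefined_is_nan_never_zero():
    p = accuracy_point(ConfusionTable(tp=0, fp=0, fn=5, tn=5))
    assert math.isnan(p.ppv)
    assert p.sensitivity == 0.0
    perfect = accuracy_point(ConfusionTable(tp=5, fp=0, fn=0, tn=5))
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv, perfect.npv) == (1, 1, 1, 1)


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
@settings(deadline=None)
def test_accuracy_matches_brute_force_counting(pairs):
    pred = [p for p, _ in pairs]
    ref = [r for _, r in pairs]
    point = accuracy_point(confusion(pred, ref))
    n_pos = sum(ref)
    if n_pos:
        assert point.sensitivity == pytest.approx(
            sum(p and r for p, r in pairs) / n_pos
        )
    if n_pos < len(pairs):
        assert point.specificity == pytest.approx(
            sum((not p) and (not r) for p, r in pairs) / (len(pairs) - n_pos)
        )


def test_odds_ratio_hand_values():
    assert odds_ratio((10, 10, 10, 10)).odds_ratio == pytest.approx(1.0)
    assert odds_ratio((20, 10, 5, 10)).odds_ratio == pytest.approx(4.0)


def test_odds_ratio_label_swap_gives_reciprocal():
    a = odds_ratio((20, 10, 5, 12))
    b = odds_ratio((5, 12, 20, 10))
    assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)


def test_odds_ratio_continuity_correction_only_with_zero_cell():
    assert not odds_ratio((20, 10, 5, 10)).continuity_corrected
    r = odds_ratio((20, 0, 5, 10))
    assert r.continuity_corrected
    assert r.odds_ratio == pytest.approx((20.5 * 10.5) / (0.5 * 5.5))


def test_odds_ratio_undefined_on_degenerate_margins():
    assert math.isnan(odds_ratio((0, 0, 5, 10)).odds_ratio)
    assert math.isnan(odds_ratio((0, 5, 0, 10)).odds_ratio)


def test_odds_ratio_ci_brackets_estimate():
    r = odds_ratio((20, 10, 5, 10))
    assert r.ci_low < r.odds_ratio < r.ci_high
    assert 0 < r.p_value < 1


@pytest.mark.parametrize(
    "scores, ref, expected",
    [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
        ([2, 2, 2, 2], [0, 1, 0, 1], 0.5),  # all ties -> 1/2
    ],
)
def test_roc_auc_hand_values(scores, ref, expected):
    assert roc_auc(scores, ref) == pytest.approx(expected)


@given(
    st.lists(st.integers(-50, 50).map(lambda v: v / 10.0), min_size=4, max_size=50),
    st.data(),
)
@settings(deadline=None, max_examples=100)
def test_roc_auc_equals_mann_whitney_and_flip(scores, data):
    n = len(scores)
    ref = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    if all(ref) or not any(ref):
        return
    scores = np.asarray(scores)
    ref = np.asarray(ref)
    u = mannwhitneyu(scores[ref], scores[~ref], alternative="two-sided").statistic
    expected = u / (ref.sum() * (~ref).sum())
    assert roc_auc(scores, ref) == pytest.approx(expected)
    assert roc_auc(scores, ref, higher_is_positive=False) == pytest.approx(1 - expected)
    # invariance under a strictly monotone transform
    assert roc_auc(np.exp(scores / 2), ref) == pytest.approx(expected)


def test_roc_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_bayes_prevalence_identity(default_cohort):
    """ppv = sens*pi / (sens*pi + (1-spec)(1-pi)) on a real classification."""
    from ogtt_screen.criteria import apply_criteria

    table = default_cohort.table
    pred = apply_criteria(table, "IADPSG2010", timing="early")["positive"]
    ref = apply_criteria(table, "IADPSG2010", timing="reference")["positive"]
    p = accuracy_point(confusion(pred, ref))
    pi = ref.astype(float).mean()
    implied = p.sensitivity * pi / (p.sensitivity * pi + (1 - p.specificity) * (1 - pi))
    assert p.ppv == pytest.approx(implied, abs=1e-12)


def test_cubic_trend_exact_and_constant():
    x = np.array([0, 1, 2, 3, 4, 5], dtype=float)
    coeffs = cubic_trend(x, x**3)
    assert coeffs == pytest.approx([0, 0, 0, 1], abs=1e-8)
    coeffs = cubic_trend(x, np.full_like(x, 2.5))
    assert coeffs == pytest.approx([2.5, 0, 0, 0], abs=1e-8)


def test_cubic_trend_matches_normal_equations():
    rng = np.random.default_rng(5)
    x = rng.uniform(-2, 2, 50)
    y = 1.5 - 0.7 * x + 0.3 * x**2 + 0.1 * x**3 + rng.normal(0, 0.2, 50)
    fitted = cubic_trend(x, y)
    design = np.vander(x, 4, increasing=True)
    oracle = np.linalg.solve(design.T @ design, design.T @ y)
    assert fitted == pytest.approx(oracle, rel=1e-8)


def test_cubic_trend_rejects_degenerate_designs():
    with pytest.raises(ValueError):
        cubic_trend([1, 2, 3, 4], [1, 2, 3, 4])  # too few points
    with pytest.raises(ValueError):
        cubic_trend([2, 2, 2, 2, 2], [1, 2, 3, 4, 5])  # all x equal
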