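"""Threshold and percentile sweep machinery."""

import numpy as np
import pytest

from ogtt_screen.accuracy import AccuracyPoint
from ogtt_screen.cohort import GeneratorParams, generate_cohort
from ogtt_screen.criteria import CRITERIA, apply_criteria
from ogtt_screen.indices import panel_frame
from ogtt_screen.sweep import (
    SweepProfile,
    combine_with_risk_factors,
    crossing_point,
    percentile_grid,
    percentile_sweep,
    scaled_cutoff_grid,
    sweep_accuracy,
)


def test_scaled_grid_step_zero_is_identity():
    grid = scaled_cutoff_grid("IADPSG2010", 5)
    assert grid[0] == CRITERIA["IADPSG2010"]


def test_scaled_grid_hand_values():
    norway = scaled_cutoff_grid("NORWAY2017", 10)[10]
    assert norway.fasting_low == pytest.approx(5.3 * 0.90)
    assert norway.two_hour_low == pytest.approx(9.0 * 0.60)
    iadpsg = scaled_cutoff_grid("IADPSG2010", 8)[8]
    assert iadpsg.fasting_low == pytest.approx(4.692)
    assert iadpsg.one_hour == pytest.approx(6.80)
    assert iadpsg.two_hour_low == pytest.approx(5.78)
    # upper (overt) bounds never scale
    assert iadpsg.fasting_high == 6.9
    assert iadpsg.two_hour_high == 11.0


def test_scaled_grid_rejects_scaling_past_zero():
    with pytest.raises(ValueError):
        scaled_cutoff_grid("WHO1999", 25)  # 25 x 4% = 100% decrease


def test_who1999_sweep_scales_only_its_two_hour_component():
    grid = scaled_cutoff_grid("WHO1999", 5)
    assert all(c.fasting_low is None and c.one_hour is None for c in grid)
    assert grid[5].two_hour_low == pytest.approx(7.8 * 0.8)


def test_sweep_self_reference_is_perfect(default_cohort):
    """Original criterion screened against itself on the same visit."""
    table = default_cohort.table
    ref = apply_criteria(table, "NORWAY2017", timing="early")["positive"]
    profile = sweep_accuracy(default_cohort, [CRITERIA["NORWAY2017"]], ref)
    assert profile.accuracy[0].sensitivity == 1.0
    assert profile.accuracy[0].specificity == 1.0


@pytest.mark.parametrize("criterion", ["WHO1999", "IADPSG2010", "NORWAY2017"])
def test_sweep_monotonicity_exact(criterion, default_cohort):
    """Nested positive sets: sens non-decreasing, spec non-increasing in k."""
    ref = apply_criteria(default_cohort.table, criterion, timing="reference")["positive"]
    profile = sweep_accuracy(default_cohort, scaled_cutoff_grid(criterion, 12), ref)
    sens = [a.sensitivity for a in profile.accuracy]
    spec = [a.specificity for a in profile.accuracy]
    assert all(b >= a for a, b in zip(sens, sens[1:]))
    assert all(b <= a for a, b in zip(spec, spec[1:]))


def test_sweep_monotonicity_on_many_random_cohorts():
    """The nesting argument holds for every cohort, not just on average."""
    for seed in range(10):
        cohort = generate_cohort(GeneratorParams(n_subjects=150, seed=100 + seed))
        ref = apply_criteria(cohort.table, "IADPSG2010", timing="reference")["positive"]
        profile = sweep_accuracy(cohort, scaled_cutoff_grid("IADPSG2010", 12), ref)
        sens = [a.sensitivity for a in profile.accuracy]
        spec = [a.specificity for a in profile.accuracy]
        assert all(b >= a for a, b in zip(sens, sens[1:]))
        assert all(b <= a for a, b in zip(spec, spec[1:]))


def test_sweep_rejects_empty_grid(default_cohort):
    with pytest.raises(ValueError):
        sweep_accuracy(default_cohort, [], [True] * len(default_cohort))


def test_percentile_grid_hand_values():
    pct, cuts = percentile_grid(np.arange(1, 101), step_percent=5)
    assert list(pct) == list(np.arange(5, 100, 5))
    # linear-interpolation percentiles of 1..100
    assert cuts == pytest.approx(np.percentile(np.arange(1, 101), pct))
    assert 0 not in pct and 100 not in pct


def test_percentile_grid_constant_marker_and_minimum_size():
    _, cuts = percentile_grid(np.full(30, 7.0))
    assert np.allclose(cuts, 7.0)
    with pytest.raises(ValueError):
        percentile_grid(np.arange(10))


def test_percentile_sweep_extremes_and_perfect_separator():
    rng = np.random.default_rng(0)
    marker = rng.normal(size=200)
    # marker is its own perfect separator, split on a grid percentile
    ref = marker > np.percentile(marker, 70)
    profile = percentile_sweep(marker, ref, higher_is_positive=True)
    assert any(
        a.sensitivity == 1.0 and a.specificity == 1.0 for a in profile.accuracy
    )
    # low cut-off on the high-risk side: everyone screened positive
    first = profile.accuracy[0]
    assert first.sensitivity == 1.0
    assert first.positives_fraction > 0.9


def test_percentile_sweep_positives_fraction_tracks_percentile():
    marker = np.arange(1000, dtype=float)
    ref = marker > 800
    profile = percentile_sweep(marker, ref, higher_is_positive=True)
    for p, acc in zip(profile.grid, profile.accuracy):
        assert acc.positives_fraction == pytest.approx((100 - p) / 100, abs=0.01)


def test_betacell_percentile_sweep_reaches_80pct_sensitivity(study_cohort):
    """Low early beta-cell function flags ~80% of future GDM near the median."""
    table = study_cohort.table
    issi = panel_frame(table, "w14")["issi2_w14"]
    ref = apply_criteria(table, "IADPSG2010", timing="reference")["positive"]
    profile = percentile_sweep(issi, ref, higher_is_positive=False)
    reaching = [p for p, a in zip(profile.grid, profile.accuracy) if a.sensitivity >= 0.8]
    assert reaching and min(reaching) <= 60  # within 10 points of the 50th percentile
    assert min(reaching) >= 40


def test_combine_with_risk_factors():
    flags = [True, False, False, False]
    bmi = [22, 30, 25, np.nan]
    age = [30, 30, 36, 30]
    out = combine_with_risk_factors(flags, bmi=bmi, age=age)
    assert out[0] == 1.0
    assert out[1] == 1.0  # bmi at the cut-off counts
    assert out[2] == 1.0  # age 36 >= 35
    assert np.isnan(out[3])  # missing covariate drops the subject
    # identity when all extra factors are off
    ident = combine_with_risk_factors(flags)
    assert list(ident) == [1.0, 0.0, 0.0, 0.0]


def test_combined_screen_is_superset(default_cohort):
    from ogtt_screen.accuracy import accuracy_point, confusion

    table = default_cohort.table
    ogtt = apply_criteria(table, "WHO2013", timing="early")["positive"]
    ref = apply_criteria(table, "WHO2013", timing="reference")["positive"]
    combined = combine_with_risk_factors(ogtt, bmi=table["bmi_early"], age=table["age"])
    a = accuracy_point(confusion(ogtt, ref))
    b = accuracy_point(confusion(combined, ref))
    assert b.sensitivity >= a.sensitivity
    assert b.specificity <= a.specificity


def _profile(sens, spec, steps=None):
    steps = steps if steps is not None else list(range(len(sens)))
    acc = [
        AccuracyPoint(s, p, 0.5, 0.5, 0.5) for s, p in zip(sens, spec)
    ]
    return SweepProfile(grid=steps, cutoffs_at_step=[None] * len(steps), accuracy=acc)


def test_crossing_point_symmetric_profile():
    prof = _profile([0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9],
                    [0.9, 0.8, 0.65, 0.5, 0.35, 0.2, 0.1])
    step, value, degenerate = crossing_point(prof)
    assert step == pytest.approx(3.0, abs=0.01)
    assert value == pytest.approx(0.5, abs=0.01)
    assert not degenerate


def test_crossing_point_degenerate_equal_profiles():
    prof = _profile([0.4] * 6, [0.4] * 6)
    step, value, degenerate = crossing_point(prof)
    assert degenerate
    assert step == pytest.approx(2.5)
    assert value == pytest.approx(0.4, abs=1e-6)


def test_crossing_point_absent_without_sign_change():
    prof = _profile([0.1, 0.15, 0.2, 0.25, 0.3, 0.35],
                    [0.9, 0.88, 0.85, 0.8, 0.78, 0.75])
    assert crossing_point(prof) is None


def test_lga_sweep_uses_same_code_path(default_cohort):
    """Targeting LGA is the identical machinery with a different reference."""
    table = default_cohort.table
    grid = scaled_cutoff_grid("IADPSG2010", 10)
    prof = sweep_accuracy(default_cohort, grid, table["lga"], target="LGA")
    assert prof.target == "LGA"
    sens = [a.sensitivity for a in prof.accuracy]
    assert all(b >= a for a, b in zip(sens, sens[1:]))
    # cross-check one step against a direct confusion computation
    from ogtt_screen.accuracy import accuracy_point, confusion

    cls = apply_criteria(table, grid[5], timing="early")["positive"]
    direct = accuracy_point(confusion(cls, table["lga"]))
    assert prof.accuracy[5] == direct
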