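"""Coupled cut-off grids and percentile sweeps for early-OGTT screening.

Two families of evaluation procedures:

* **scaled-cutoff sweep** — the diagnostic thresholds are incrementally
  down-adjusted, coupled per step: the fasting bound falls by 1% per step
  and the 60/120-minute bounds by 4% per step (compensating the smaller
  gestational rise of fasting glucose), and the early (14-16 week) OGTT is
  re-classified at every step against a fixed reference label (a late-visit
  GDM diagnosis, or LGA birth);
* **percentile sweep** — a continuous marker (beta-cell function, AUC
  glucose, fasting glucose) is thresholded at whole-population percentiles
  on a 5%-step grid.

Both emit a :class:`SweepProfile` of accuracy points along the grid, which
:func:`crossing_point` smooths with cubic fits to locate where sensitivity
and specificity cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ogtt_screen.accuracy import AccuracyPoint, accuracy_point, confusion, cubic_trend
from ogtt_screen.criteria import CriterionSet, apply_criteria, get_criterion

FASTING_STEP = 0.01   # fractional decrease of the fasting bound per grid step
POSTLOAD_STEP = 0.04  # fractional decrease of the 60/120-min bounds per step
DEFAULT_N_STEPS = 12


@dataclass
class SweepProfile:
    """Accuracy terms along an ordered cut-off grid."""

    grid: list            # percent-decrease step k, or percentile p
    cutoffs_at_step: list  # CriterionSet per step, or marker cut-off value
    accuracy: list        # AccuracyPoint per step
    criterion_name: str = ""
    target: str = "GDM"
    kind: str = "scaled"  # "scaled" or "percentile"

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.accuracy):
            raise ValueError("one accuracy point per grid step required")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ordered")

    def frame(self) -> pd.DataFrame:
        """Tidy table: one row per grid step."""
        rows = []
        for g, cut, acc in zip(self.grid, self.cutoffs_at_step, self.accuracy):
            row = {"step": g, "criterion": self.criterion_name, "target": self.target}
            if isinstance(cut, CriterionSet):
                row.update(
                    fasting_cutoff=cut.fasting_low,
                    one_hour_cutoff=cut.one_hour,
                    two_hour_cutoff=cut.two_hour_low,
                )
            else:
                row["cutoff"] = cut
            row.update(
                sensitivity=acc.sensitivity,
                specificity=acc.specificity,
                ppv=acc.ppv,
                npv=acc.npv,
                positives_fraction=acc.positives_fraction,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def scaled_cutoff_grid(criterion: CriterionSet | str, n_steps: int = DEFAULT_N_STEPS) -> list[CriterionSet]:
    """Criterion variants at coupled percent decreases, step k = 0..n_steps.

    Step k multiplies the fasting lower bound by (1 - 0.01 k) and the 60-
    and 120-minute bounds by (1 - 0.04 k); overt-diabetes upper bounds and
    the early-FPG shortcut stay fixed. Scaling any bound past zero is
    rejected.
    """
    if isinstance(criterion, str):
        criterion = get_criterion(criterion)
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if 1 - POSTLOAD_STEP * n_steps <= 0 or 1 - FASTING_STEP * n_steps <= 0:
        raise ValueError("grid scales a threshold past zero; shorten it")
    return [
        criterion.scaled(1 - FASTING_STEP * k, 1 - POSTLOAD_STEP * k)
        for k in range(n_steps + 1)
    ]


def sweep_accuracy(cohort, grid: list[CriterionSet], reference,
                   screen_visit: str = "w14", target: str = "GDM") -> SweepProfile:
    """Accuracy of the early OGTT at every step of a cut-off grid.

    ``reference`` is a fixed per-subject flag vector (late-visit GDM label
    or LGA birth); the screen is re-classified under each scaled criterion
    at ``screen_visit`` and cross-tabulated against it.
    """
    if not grid:
        raise ValueError("empty cut-off grid")
    table = cohort.table if hasattr(cohort, "table") else cohort
    timing = "early" if screen_visit == "w14" else "reference"
    points = []
    for crit in grid:
        cls = apply_criteria(table, crit, timing=timing)
        points.append(accuracy_point(confusion(cls["positive"], reference)))
    return SweepProfile(
        grid=list(range(len(grid))),
        cutoffs_at_step=list(grid),
        accuracy=points,
        criterion_name=grid[0].name,
        target=target,
        kind="scaled",
    )


def percentile_grid(marker, step_percent: float = 5.0):
    """Cut-offs at whole-population percentiles of a marker.

    Percentiles run from ``step_percent`` to ``100 - step_percent`` in
    steps of ``step_percent`` (the degenerate 0th/100th endpoints are
    excluded); values use linear interpolation between order statistics.

    Returns
    -------
    (percentiles, cutoffs) : (ndarray, ndarray)
    """
    marker = np.asarray(marker, dtype=float)
    marker = marker[~np.isnan(marker)]
    if marker.size < 20:
        raise ValueError("need at least 20 defined marker values")
    if not 0 < step_percent < 100:
        raise ValueError("step_percent must lie in (0, 100)")
    pct = np.arange(step_percent, 100, step_percent)
    return pct, np.percentile(marker, pct)


def percentile_sweep(marker, reference, higher_is_positive: bool = True,
                     step_percent: float = 5.0, marker_name: str = "",
                     target: str = "GDM") -> SweepProfile:
    """Accuracy at every population-percentile cut-off of a marker.

    ``higher_is_positive`` encodes the risk orientation: glucose-like
    markers flag subjects at or above the cut-off, beta-cell function
    flags subjects at or below it. Subjects with an undefined marker or
    reference are dropped.
    """
    marker = np.asarray(marker, dtype=float)
    from ogtt_screen.accuracy import _as_flag_array

    ref = _as_flag_array(reference)
    keep = ~(np.isnan(marker) | np.isnan(ref))
    marker, ref = marker[keep], ref[keep].astype(bool)
    pct, cuts = percentile_grid(marker, step_percent)
    points = []
    for c in cuts:
        flags = marker >= c if higher_is_positive else marker <= c
        points.append(accuracy_point(confusion(flags, ref)))
    return SweepProfile(
        grid=list(pct),
        cutoffs_at_step=list(cuts),
        accuracy=points,
        criterion_name=marker_name,
        target=target,
        kind="percentile",
    )


def combine_with_risk_factors(ogtt_positive, bmi=None, age=None,
                              bmi_cut: float = 30.0, age_cut: float = 35.0):
    """Disjunction of an OGTT screen with BMI and/or age risk factors.

    A subject is positive if OGTT-positive OR (bmi >= bmi_cut) OR
    (age >= age_cut); each factor is toggled off by passing ``None``.
    Subjects missing a requested covariate are dropped (``nan`` result).
    """
    from ogtt_screen.accuracy import _as_flag_array

    flags = _as_flag_array(ogtt_positive)
    combined = flags.copy()
    for values, cut in ((bmi, bmi_cut), (age, age_cut)):
        if values is None:
            continue
        v = np.asarray(values, dtype=float)
        combined = np.where(np.isnan(v) | np.isnan(combined), np.nan,
                            np.maximum(combined, (v >= cut).astype(float)))
    return combined


def crossing_point(profile: SweepProfile):
    """Smoothed sensitivity/specificity crossing along a sweep grid.

    Cubic trends are fitted to sensitivity and specificity versus the grid
    step; the crossing is the root of the difference of fits inside the
    grid range, preferring the root nearest the raw sign change. Returns
    ``(step, value, degenerate)`` or ``None`` when the profiles never
    cross. ``degenerate`` marks the everywhere-equal case, reported at
    mid-grid.
    """
    x = np.asarray(profile.grid, dtype=float)
    sens = np.asarray([a.sensitivity for a in profile.accuracy], dtype=float)
    spec = np.asarray([a.specificity for a in profile.accuracy], dtype=float)
    keep = ~(np.isnan(sens) | np.isnan(spec))
    x, sens, spec = x[keep], sens[keep], spec[keep]
    if x.size < 5:
        raise ValueError("profile too short to smooth")
    diff = sens - spec
    if np.allclose(diff, 0.0):
        mid = 0.5 * (x[0] + x[-1])
        c = cubic_trend(x, sens)
        return float(mid), float(np.polynomial.polynomial.polyval(mid, c)), True
    signs = np.sign(diff)
    nz = signs[signs != 0]
    if nz.size and np.all(nz == nz[0]) and not np.any(signs == 0):
        return None  # no sign change anywhere on the grid

    c_sens = cubic_trend(x, sens)
    c_spec = cubic_trend(x, spec)
    roots = np.polynomial.polynomial.polyroots(c_sens - c_spec)
    real = roots[np.abs(roots.imag) < 1e-9].real
    inside = real[(real >= x[0]) & (real <= x[-1])]
    if inside.size == 0:
        return None
    # raw sign-change location as the anchor for root selection
    change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    anchor = x[change[0]] if change.size else 0.5 * (x[0] + x[-1])
    root = float(inside[np.argmin(np.abs(inside - anchor))])
    value = float(np.polynomial.polynomial.polyval(root, 0.5 * (c_sens + c_spec)))
    return root, value, False
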