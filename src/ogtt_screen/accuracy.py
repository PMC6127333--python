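"""Diagnostic-accuracy machinery: 2x2 tables, odds ratios, ROC, trend fits.

Conventions:

* sensitivity = TP / (TP + FN), specificity = TN / (FP + TN),
  PPV = TP / (TP + FP), NPV = TN / (FN + TN);
* a 0/0 ratio is *undefined* and serialized as ``nan``, never coerced to
  0 or 1 (sweep endpoints routinely empty one margin of the table);
* odds-ratio confidence intervals use the Woolf log-OR normal
  approximation, with a +0.5 continuity correction applied to every cell
  iff any cell is zero; the p-value is a two-sided Wald test on the
  log odds ratio;
* ROC AUC is the Mann-Whitney concordance probability with ties counted
  one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import stats
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyPoint:
    """Derived accuracy terms; ``nan`` marks an undefined (0/0) entry."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    positives_fraction: float


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool
    method: str = "woolf"  # CI construction recorded in output metadata


def confusion(predicted, reference) -> ConfusionTable:
    """Cross-tabulate predicted against reference flags.

    Pairs where either flag is missing (``nan`` / ``None`` / pandas NA)
    are dropped; at least one evaluable pair is required.
    """
    pred = _as_flag_array(predicted)
    ref = _as_flag_array(reference)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference must align")
    keep = ~(np.isnan(pred) | np.isnan(ref))
    if not keep.any():
        raise ValueError("no evaluable subject pairs")
    p = pred[keep].astype(bool)
    r = ref[keep].astype(bool)
    return ConfusionTable(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def _as_flag_array(flags) -> np.ndarray:
    """Coerce flag input (bool/int/float/pandas nullable) to {0, 1, nan}."""
    import pandas as pd

    s = pd.Series(flags)
    na = s.isna().to_numpy()
    vals = np.asarray([False if m else bool(v) for m, v in zip(na, s)], dtype=float)
    return np.where(na, np.nan, vals)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def accuracy_point(t: ConfusionTable) -> AccuracyPoint:
    """Sensitivity, specificity, PPV, NPV and screened-positive fraction."""
    return AccuracyPoint(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.fp + t.tn),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.fn + t.tn),
        positives_fraction=_ratio(t.tp + t.fp, t.total),
    )


def odds_ratio(table) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf 95% CI and Wald p-value.

    Accepts a :class:`ConfusionTable` or any (a, b, c, d) quadruple laid
    out as rows = exposure, columns = outcome. Two zero cells in the same
    row or column leave the ratio undefined.
    """
    if isinstance(table, ConfusionTable):
        a, b, c, d = table.tp, table.fp, table.fn, table.tn
    else:
        a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), float("nan"), False)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        continuity_corrected=corrected,
    )


def roc_auc(scores, reference, higher_is_positive: bool = True) -> float:
    """Area under the ROC curve for a continuous marker.

    Equals the Mann-Whitney U statistic divided by ``n1 * n2`` with ties
    counted one half. Both classes must be present; pairs with a missing
    score or label are dropped.
    """
    s = np.asarray(scores, dtype=float)
    r = _as_flag_array(reference)
    keep = ~(np.isnan(s) | np.isnan(r))
    s, r = s[keep], r[keep].astype(bool)
    if r.all() or not r.any():
        raise ValueError("both outcome classes must be present")
    auc = float(roc_auc_score(r, s))
    return auc if higher_is_positive else 1.0 - auc


def cubic_trend(x, y) -> np.ndarray:
    """Least-squares third-order polynomial fit.

    Returns the four coefficients in ascending order (c0, c1, c2, c3),
    i.e. ``y ~ c0 + c1 x + c2 x^2 + c3 x^3``. Used to smooth sweep
    profiles before locating the sensitivity/specificity crossing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("cubic trend needs at least 5 points")
    if np.ptp(x) == 0:
        raise ValueError("design is rank-deficient: all x equal")
    return P.polyfit(x, y, 3)
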