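"""OGTT-derived metabolic indices.

All indices are computed from a single 75 g oral glucose tolerance test
with samples at 0, 30, 60, 90 and 120 minutes, glucose in mmol/L and
insulin in mU/L:

* trapezoidal areas under the glucose and insulin curves (``AUC``),
* the Matsuda whole-body insulin-sensitivity index,
* HOMA-IR (fasting insulin resistance),
* ISSI-2, the insulin secretion-sensitivity index used as the measure of
  beta-cell function, and
* the insulinogenic index (early-phase insulin secretion).

AUC time unit
-------------
Areas are reported in concentration x 30-minute units: adjacent standard
timepoints are one unit apart, so a flat curve at ``c`` over 0-120 min has
an AUC of ``4 c``. This convention makes the AUC of glucose roughly four
times the mean glucose, matching the magnitude of published summary
tables. Pass ``unit="min"`` or ``unit="hour"`` for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Standard OGTT sampling grid (minutes after the 75 g load).
TIMEPOINTS: tuple[int, ...] = (0, 30, 60, 90, 120)

#: Divisors converting a minute-scale trapezoid integral to each unit.
_UNIT_DIVISORS = {"30min": 30.0, "min": 1.0, "hour": 60.0}

#: Flat-curve product of Matsuda and HOMA-IR (10000 / 22.5).
FLAT_CURVE_PRODUCT = 10000.0 / 22.5


@dataclass(frozen=True)
class OGTTVisit:
    """One visit's glucose/insulin curves on the standard grid.

    Parameters
    ----------
    visit_label : str
        One of ``w14`` (weeks 14-16), ``w30`` (weeks 30-32) or ``y5``
        (5-year postpartum follow-up).
    glucose : array-like of float
        Glucose (mmol/L) per timepoint; ``nan`` marks a missing sample.
    insulin : array-like of float
        Insulin (mU/L) per timepoint; post-load insulin may be entirely
        missing at the follow-up visit.
    times : tuple of int
        Sampling times in minutes, strictly increasing; fasting (t=0)
        must be present.
    """

    visit_label: str
    glucose: tuple[float, ...]
    insulin: tuple[float, ...]
    times: tuple[int, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if len(self.times) != len(self.glucose) or len(self.times) != len(self.insulin):
            raise ValueError("glucose/insulin length must match the time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0 or not np.isfinite(self.glucose[0]):
            raise ValueError("fasting (t=0) glucose must be present")

    @property
    def fasting_glucose(self) -> float:
        return self.glucose[0]

    @property
    def fasting_insulin(self) -> float:
        return self.insulin[0]

    def value_at(self, minute: int, series: str = "glucose") -> float:
        """Return the sample at ``minute`` or ``nan`` if not on the grid."""
        arr = self.glucose if series == "glucose" else self.insulin
        for t, v in zip(self.times, arr):
            if t == minute:
                return v
        return float("nan")


@dataclass(frozen=True)
class IndexPanel:
    """All indices derived from one visit; ``nan`` marks undefined entries."""

    auc_glucose: float
    auc_insulin: float
    matsuda: float
    homa_ir: float
    issi2: float
    igi: float


def auc_trapezoid(values, times=TIMEPOINTS, unit: str = "30min") -> float:
    """Trapezoidal area under a sampled concentration curve.

    Parameters
    ----------
    values : array-like
        Concentrations at each timepoint.
    times : array-like
        Sampling times in minutes, strictly increasing, at least two.
    unit : {"30min", "min", "hour"}
        Time unit of the returned area. The default expresses adjacent
        standard timepoints as one unit apart.

    Returns
    -------
    float
        Area in concentration x ``unit``; ``nan`` if any value is missing.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two timepoints for a trapezoid")
    if values.size != times.size:
        raise ValueError("values and times must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if unit not in _UNIT_DIVISORS:
        raise ValueError(f"unknown AUC unit {unit!r}")
    if np.any(~np.isfinite(values)):
        return float("nan")
    return float(np.trapezoid(values, x=times) / _UNIT_DIVISORS[unit])


def matsuda(fasting_glu: float, fasting_ins: float, mean_glu: float, mean_ins: float) -> float:
    """Matsuda whole-body insulin sensitivity index.

    ``10000 / sqrt(fasting glucose x fasting insulin x mean glucose x
    mean insulin)`` with glucose in mmol/L and insulin in mU/L; the means
    are unweighted arithmetic means of the five OGTT timepoints.
    """
    inputs = np.asarray([fasting_glu, fasting_ins, mean_glu, mean_ins], dtype=float)
    if np.any(np.isnan(inputs)):
        return float("nan")
    if np.any(inputs <= 0):
        raise ValueError("matsuda requires strictly positive inputs")
    return float(1e4 / np.sqrt(np.prod(inputs)))


def homa_ir(fasting_glu: float, fasting_ins: float) -> float:
    """HOMA insulin resistance: fasting insulin x fasting glucose / 22.5."""
    if np.isnan(fasting_glu) or np.isnan(fasting_ins):
        return float("nan")
    if fasting_glu <= 0 or fasting_ins <= 0:
        raise ValueError("homa_ir requires strictly positive inputs")
    return float(fasting_ins * fasting_glu / 22.5)


def issi2(auc_ins: float, auc_glu: float, matsuda_index: float) -> float:
    """Insulin secretion-sensitivity index-2 (beta-cell function).

    ``(AUC insulin / AUC glucose) x Matsuda``, both areas over 0-120 min
    in the same time unit.
    """
    inputs = np.asarray([auc_ins, auc_glu, matsuda_index], dtype=float)
    if np.any(np.isnan(inputs)):
        return float("nan")
    if np.any(inputs <= 0):
        raise ValueError("issi2 requires strictly positive inputs")
    return float(auc_ins / auc_glu * matsuda_index)


def insulinogenic_index(glu0: float, glu30: float, ins0: float, ins30: float) -> float:
    """Insulinogenic index (Ins30 - Ins0) / (Glu30 - Glu0).

    A zero glucose increment makes the ratio undefined; the result is
    ``nan`` (the subject is kept for the other indices, not dropped).
    """
    vals = np.asarray([glu0, glu30, ins0, ins30], dtype=float)
    if np.any(np.isnan(vals)):
        return float("nan")
    if glu30 == glu0:
        return float("nan")
    return float((ins30 - ins0) / (glu30 - glu0))


def index_panel(visit: OGTTVisit, unit: str = "30min") -> IndexPanel:
    """Compute every index a visit's available samples support.

    Indices whose inputs are missing come back ``nan``: the AUCs and
    Matsuda need the full five-point curve, HOMA-IR only the fasting
    sample, the insulinogenic index the 0 and 30 minute samples.
    """
    glu = np.asarray(visit.glucose, dtype=float)
    ins = np.asarray(visit.insulin, dtype=float)

    full_glu = bool(np.all(np.isfinite(glu)))
    full_ins = bool(np.all(np.isfinite(ins)))

    auc_g = auc_trapezoid(glu, visit.times, unit) if full_glu else float("nan")
    auc_i = auc_trapezoid(ins, visit.times, unit) if full_ins else float("nan")

    if np.isfinite(visit.fasting_insulin):
        homa = homa_ir(visit.fasting_glucose, visit.fasting_insulin)
    else:
        homa = float("nan")

    if full_glu and full_ins:
        mats = matsuda(glu[0], ins[0], float(glu.mean()), float(ins.mean()))
        issi = issi2(auc_i, auc_g, mats)
    else:
        mats = float("nan")
        issi = float("nan")

    igi = insulinogenic_index(
        visit.value_at(0, "glucose"),
        visit.value_at(30, "glucose"),
        visit.value_at(0, "insulin"),
        visit.value_at(30, "insulin"),
    )
    return IndexPanel(
        auc_glucose=auc_g,
        auc_insulin=auc_i,
        matsuda=mats,
        homa_ir=homa,
        issi2=issi,
        igi=igi,
    )


def panel_frame(table, visit: str, unit: str = "30min"):
    """Vectorized index panel for every subject at one visit.

    Parameters
    ----------
    table : pandas.DataFrame
        Wide cohort table with ``glu_{visit}_{t}`` and ``ins_{visit}_{t}``
        columns on the standard grid.
    visit : str
        Visit label (``w14``, ``w30`` or ``y5``).

    Returns
    -------
    pandas.DataFrame
        One row per subject with columns ``auc_glucose, auc_insulin,
        matsuda, homa_ir, issi2, igi`` suffixed by the visit label,
        indexed like ``table``. Undefined entries are ``NaN``.
    """
    import pandas as pd

    glu = table[[f"glu_{visit}_{t}" for t in TIMEPOINTS]].to_numpy(dtype=float)
    ins = table[[f"ins_{visit}_{t}" for t in TIMEPOINTS]].to_numpy(dtype=float)

    div = _UNIT_DIVISORS[unit]
    times = np.asarray(TIMEPOINTS, dtype=float)
    auc_g = np.trapezoid(glu, x=times, axis=1) / div
    auc_i = np.trapezoid(ins, x=times, axis=1) / div

    with np.errstate(invalid="ignore", divide="ignore"):
        mats = 1e4 / np.sqrt(glu[:, 0] * ins[:, 0] * glu.mean(axis=1) * ins.mean(axis=1))
        homa = ins[:, 0] * glu[:, 0] / 22.5
        issi_arr = auc_i / auc_g * mats
        dglu = glu[:, 1] - glu[:, 0]
        igi = np.where(dglu != 0, (ins[:, 1] - ins[:, 0]) / dglu, np.nan)

    return pd.DataFrame(
        {
            f"auc_glucose_{visit}": auc_g,
            f"auc_insulin_{visit}": auc_i,
            f"matsuda_{visit}": mats,
            f"homa_ir_{visit}": homa,
            f"issi2_{visit}": issi_arr,
            f"igi_{visit}": igi,
        },
        index=table.index,
    )
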