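"""Rule engines for gestational-diabetes and pre-diabetes diagnosis.

Four GDM criteria are shipped (WHO1999, IADPSG2010, WHO2013, Norway2017)
plus the ADA pre-diabetes rule applied at the 5-year follow-up OGTT. Each
criterion is a boolean OR over glucose components; every comparison is
inclusive at the printed lower bound. Where a criterion prints a range
(e.g. fasting 5.1-6.9 mmol/L) the upper bound marks the boundary to overt
diabetes: values above it set ``overt_flag`` and are reported separately,
but still classify as positive so that raising a glucose value can never
turn a positive test negative.

The registry lives in ``data/criteria.yaml`` so the sweep machinery can
derive scaled variants of the same rule sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

GDM_CRITERIA = ("WHO1999", "IADPSG2010", "WHO2013", "NORWAY2017")


@dataclass(frozen=True)
class CriterionSet:
    """A named set of inclusive glucose thresholds (mmol/L).

    ``timing`` declares which visits the reference diagnosis may use:
    ``late`` (30-32 week OGTT only), ``any`` (either pregnancy OGTT) or
    ``y5`` (postpartum follow-up). ``uses_early_fpg`` adds the IADPSG2010
    shortcut that an early-pregnancy fasting glucose in the fasting range
    is itself diagnostic.
    """

    name: str
    fasting_low: float | None = None
    fasting_high: float | None = None
    one_hour: float | None = None
    two_hour_low: float | None = None
    two_hour_high: float | None = None
    timing: str = "late"
    uses_early_fpg: bool = False

    def __post_init__(self) -> None:
        if self.fasting_low is None and self.one_hour is None and self.two_hour_low is None:
            raise ValueError(f"{self.name}: at least one threshold required")
        for lo, hi in ((self.fasting_low, self.fasting_high), (self.two_hour_low, self.two_hour_high)):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{self.name}: lower bound exceeds upper bound")

    def scaled(self, fasting_factor: float, postload_factor: float) -> "CriterionSet":
        """Return a copy with lower bounds multiplied by the given factors.

        The fasting factor applies to the fasting lower bound, the
        post-load factor to the 60- and 120-minute thresholds. Upper
        (overt-diabetes) bounds and the early-FPG shortcut are unchanged.
        """
        if fasting_factor <= 0 or postload_factor <= 0:
            raise ValueError("scale factors must stay positive")
        kw = {}
        if self.fasting_low is not None:
            kw["fasting_low"] = self.fasting_low * fasting_factor
        if self.one_hour is not None:
            kw["one_hour"] = self.one_hour * postload_factor
        if self.two_hour_low is not None:
            kw["two_hour_low"] = self.two_hour_low * postload_factor
        return replace(self, **kw)


@dataclass(frozen=True)
class Classification:
    """Outcome of applying one criterion to one subject."""

    subject_id: object
    positive: bool | None  # None = undefined (required samples missing)
    trigger: str  # "fasting" / "1h" / "2h" / "early-fpg" / ""
    visit_used: str
    overt_flag: bool


def _load_registry() -> dict[str, CriterionSet]:
    text = resources.files("ogtt_screen").joinpath("data/criteria.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: CriterionSet(name=name, **fields) for name, fields in raw.items()}


#: Shipped criteria registry, keyed by name.
CRITERIA: dict[str, CriterionSet] = _load_registry()


def get_criterion(name: str) -> CriterionSet:
    try:
        return CRITERIA[name]
    except KeyError:
        raise KeyError(f"unknown criterion {name!r}; known: {sorted(CRITERIA)}") from None


def _components(criterion: CriterionSet, fasting, one_h, two_h, early_fpg=None):
    """Boolean component fires on the vectorized glucose arrays.

    Returns (fired, evaluable, overt) arrays per component in trigger
    priority order: fasting, 1h, 2h, early-fpg.
    """
    comps = []
    if criterion.fasting_low is not None:
        comps.append(("fasting", fasting, criterion.fasting_low, criterion.fasting_high))
    if criterion.one_hour is not None:
        comps.append(("1h", one_h, criterion.one_hour, None))
    if criterion.two_hour_low is not None:
        comps.append(("2h", two_h, criterion.two_hour_low, criterion.two_hour_high))
    if criterion.uses_early_fpg and early_fpg is not None:
        comps.append(("early-fpg", early_fpg, criterion.fasting_low, criterion.fasting_high))
    out = []
    for label, values, low, high in comps:
        values = np.asarray(values, dtype=float)
        present = np.isfinite(values)
        fired = present & (values >= low)
        overt = fired & (values > high) if high is not None else np.zeros_like(fired)
        out.append((label, fired, present, overt))
    return out


def classify(visit, criterion: CriterionSet, early_fpg: float | None = None,
             subject_id=0) -> Classification:
    """Classify a single visit under one criterion.

    ``early_fpg`` is the 14-16 week fasting glucose used by the IADPSG2010
    early-pregnancy shortcut; it is ignored by criteria that do not use it.
    Missing required samples make the classification undefined
    (``positive is None``) unless some other component already fired.
    """
    comps = _components(
        criterion,
        [visit.value_at(0, "glucose")],
        [visit.value_at(60, "glucose")],
        [visit.value_at(120, "glucose")],
        None if early_fpg is None else [early_fpg],
    )
    fired = [c for c in comps if bool(c[1][0])]
    all_evaluable = all(bool(c[2][0]) for c in comps)
    overt = any(bool(c[3][0]) for c in comps)
    if fired:
        return Classification(subject_id, True, fired[0][0], visit.visit_label, overt)
    if not all_evaluable:
        return Classification(subject_id, None, "", visit.visit_label, False)
    return Classification(subject_id, False, "", visit.visit_label, False)


def _classify_columns(table: pd.DataFrame, visit: str, criterion: CriterionSet,
                      early_fpg=None):
    fasting = table.get(f"glu_{visit}_0", pd.Series(np.nan, index=table.index))
    one_h = table.get(f"glu_{visit}_60", pd.Series(np.nan, index=table.index))
    two_h = table.get(f"glu_{visit}_120", pd.Series(np.nan, index=table.index))
    comps = _components(criterion, fasting, one_h, two_h, early_fpg)
    n = len(table)
    positive = np.zeros(n, dtype=bool)
    evaluable = np.ones(n, dtype=bool)
    overt = np.zeros(n, dtype=bool)
    trigger = np.full(n, "", dtype=object)
    for label, fired, present, ov in comps:
        newly = fired & (trigger == "")
        trigger[newly] = label
        positive |= fired
        evaluable &= present
        overt |= ov
    undefined = ~positive & ~evaluable
    return positive, undefined, trigger, overt


def apply_criteria(cohort, criterion: CriterionSet | str, timing: str = "reference") -> pd.DataFrame:
    """Apply one criterion to every subject of a cohort.

    Parameters
    ----------
    cohort : Cohort or pandas.DataFrame
        Wide cohort table (``glu_{visit}_{t}`` columns).
    criterion : CriterionSet or str
        Rule set, or its name in the shipped registry.
    timing : {"reference", "early", "y5"}
        ``reference`` diagnoses GDM from the 30-32 week OGTT, extended by
        the criterion's own timing rules (WHO2013 may use either pregnancy
        OGTT; IADPSG2010 adds the early fasting-glucose shortcut).
        ``early`` screens with the 14-16 week OGTT alone. ``y5`` applies
        the rule to the follow-up OGTT (pre-diabetes).

    Returns
    -------
    pandas.DataFrame
        Columns ``positive`` (nullable boolean; <NA> when required samples
        are missing), ``trigger``, ``visit_used`` and ``overt_flag``,
        indexed like the cohort table.
    """
    table = cohort.table if hasattr(cohort, "table") else cohort
    if len(table) == 0:
        raise ValueError("empty cohort")
    if isinstance(criterion, str):
        criterion = get_criterion(criterion)

    if timing == "y5" or criterion.timing == "y5":
        pos, und, trig, overt = _classify_columns(table, "y5", criterion)
        visit_used = "y5"
    elif timing == "early":
        pos, und, trig, overt = _classify_columns(table, "w14", criterion)
        visit_used = "w14"
    elif timing == "reference":
        early_fpg = table.get("glu_w14_0") if criterion.uses_early_fpg else None
        pos, und, trig, overt = _classify_columns(table, "w30", criterion, early_fpg)
        visit_used = "w30"
        if criterion.timing == "any":
            pos2, und2, trig2, overt2 = _classify_columns(table, "w14", criterion)
            newly = pos2 & ~pos
            trig[newly] = [t + "@w14" for t in trig2[newly]]
            pos |= pos2
            und &= und2
            overt |= overt2
            visit_used = "any"
    else:
        raise ValueError(f"unknown timing policy {timing!r}")

    positive = pd.array(pos, dtype="boolean")
    positive[und] = pd.NA
    return pd.DataFrame(
        {
            "positive": positive,
            "trigger": trig,
            "visit_used": visit_used,
            "overt_flag": overt,
        },
        index=table.index,
    )


def reference_labels(cohort, criterion_names=GDM_CRITERIA) -> pd.DataFrame:
    """Reference GDM label per criterion (nullable boolean columns)."""
    table = cohort.table if hasattr(cohort, "table") else cohort
    return pd.DataFrame(
        {name: apply_criteria(table, name, timing="reference")["positive"] for name in criterion_names},
        index=table.index,
    )
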