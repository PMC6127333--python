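"""Synthetic pregnancy-cohort generator with correlated OGTT biomarkers.

Emulates the distributional structure of a prospective low-risk pregnancy
cohort given a 75 g OGTT at 14-16 and 30-32 weeks of gestation and an
optional 5-year postpartum follow-up OGTT:

* glucose and insulin are jointly log-normal (guaranteeing positivity and
  the right-skewed median/IQR summaries such cohorts report), with a
  latent factor structure that plants, exactly, a chosen within-curve
  correlation, per-timepoint cross-visit glucose correlations and a
  glucose-insulin coupling;
* gestational diabetes is *emergent*: no GDM label is planted, prevalence
  under each diagnostic criterion follows from the calibrated glucose
  distributions;
* large-for-gestational-age (LGA) birth is drawn from a logistic model in
  standardized late-visit AUC glucose;
* 5-year pre-diabetes is drawn from a logistic model in standardized log
  beta-cell function (ISSI-2) at 14-16 weeks, and the follow-up fasting /
  2 h glucose values are then generated consistently with the drawn flag.

Determinism: one global seed; all draws flow from numpy Generator streams
spawned from that seed in documented order (curves and demographics first,
then outcomes), so equal parameters reproduce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri

from ogtt_screen.indices import TIMEPOINTS, panel_frame

VISITS = ("w14", "w30", "y5")

#: Default natural-scale medians (mmol/L) per timepoint, calibrated so the
#: emergent GDM prevalences and AUC-glucose medians match a low-risk
#: Scandinavian pregnancy cohort (see docs/methods.md).
DEFAULT_GLUCOSE_MEDIANS = {
    "w14": (4.60, 5.90, 5.50, 4.73, 5.35),
    "w30": (4.75, 7.10, 7.35, 6.42, 6.40),
}
DEFAULT_INSULIN_MEDIANS = {
    "w14": (3.65, 45.0, 40.0, 25.0, 15.0),
    "w30": (5.30, 80.0, 75.0, 50.0, 28.0),
}


def _tuple5(x) -> tuple[float, ...]:
    t = tuple(float(v) for v in x)
    if len(t) != len(TIMEPOINTS):
        raise ValueError(f"expected {len(TIMEPOINTS)} per-timepoint values, got {len(t)}")
    return t


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic cohort generator.

    Correlations are planted on the log scale through a latent factor
    model; log-normal location parameters are expressed as natural-scale
    medians (location = ln median). See docs/methods.md for the factor
    decomposition and the calibration targets behind the defaults.
    """

    n_subjects: int = 1031
    seed: int = 0

    # log-normal medians per visit/timepoint (mmol/L, mU/L)
    glucose_medians: dict = field(default_factory=lambda: dict(DEFAULT_GLUCOSE_MEDIANS))
    insulin_medians: dict = field(default_factory=lambda: dict(DEFAULT_INSULIN_MEDIANS))
    # log-scale SDs per timepoint (shared by the two pregnancy visits)
    glucose_log_sd: tuple = (0.075, 0.20, 0.22, 0.20, 0.18)
    insulin_log_sd: tuple = (0.55, 0.55, 0.55, 0.55, 0.55)

    # correlation structure (log scale)
    within_curve_corr: float = 0.60          # glucose timepoints within a visit
    insulin_within_curve_corr: float = 0.65
    cross_visit_corr: tuple = (0.54, 0.48, 0.54, 0.58, 0.50)  # same-timepoint glucose
    shared_time_corr: float = 0.40           # cross-visit, cross-timepoint glucose
    insulin_cross_visit_corr: float = 0.35
    glu_ins_subject_corr: float = 0.75       # coupling of subject-level factors
    glu_ins_visit_corr: float = 0.40         # coupling of visit-level factors

    # demographics
    age_mean: float = 31.2
    age_sd: float = 3.8
    age_glucose_corr: float = 0.10
    bmi_log_median_early: float = 23.8
    bmi_log_median_late: float = 26.5
    bmi_log_sd: float = 0.134
    bmi_glucose_corr: float = 0.40

    # outcome models
    lga_base_rate: float = 0.138
    lga_log_or_per_sd_aucglu: float = 0.35
    prediab_base_rate: float = 20 / 300
    prediab_log_or_per_sd_betacell: float = math.log(0.34)

    # follow-up visit marginals (postpartum, mmol/L / mU/L)
    y5_glucose_medians: tuple = (4.90, 6.60, 6.20, 5.60, 5.30)
    y5_glucose_log_sd: tuple = (0.07, 0.16, 0.18, 0.16, 0.14)
    y5_fasting_insulin_median: float = 6.0
    y5_fasting_insulin_log_sd: float = 0.55

    # missingness switches
    missing_early_fraction: float = 0.0   # subjects without the 14-16 week OGTT
    follow_up_fraction: float = 1.0       # subjects with a 5-year visit

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("lga_base_rate", "prediab_base_rate"):
            r = getattr(self, name)
            if not 0 < r < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("missing_early_fraction",):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 < self.follow_up_fraction <= 1:
            raise ValueError("follow_up_fraction must lie in (0, 1]")
        object.__setattr__(self, "glucose_log_sd", _tuple5(self.glucose_log_sd))
        object.__setattr__(self, "insulin_log_sd", _tuple5(self.insulin_log_sd))
        object.__setattr__(self, "cross_visit_corr", _tuple5(self.cross_visit_corr))
        object.__setattr__(self, "y5_glucose_medians", _tuple5(self.y5_glucose_medians))
        object.__setattr__(self, "y5_glucose_log_sd", _tuple5(self.y5_glucose_log_sd))
        gm = {v: _tuple5(self.glucose_medians[v]) for v in ("w14", "w30")}
        im = {v: _tuple5(self.insulin_medians[v]) for v in ("w14", "w30")}
        object.__setattr__(self, "glucose_medians", gm)
        object.__setattr__(self, "insulin_medians", im)
        self._loadings()  # validates feasibility of the correlation structure

    def _loadings(self):
        """Factor-model loadings; raises if the requested correlations are
        jointly infeasible (the analogue of a non-positive-definite block)."""
        a2 = self.shared_time_corr
        d2 = self.within_curve_corr - a2
        if d2 < 0:
            raise ValueError(
                "infeasible glucose correlations: shared_time_corr "
                f"({a2}) exceeds within_curve_corr ({self.within_curve_corr})"
            )
        c2 = np.asarray(self.cross_visit_corr) - a2
        if np.any(c2 < 0):
            raise ValueError(
                "infeasible glucose correlations: shared_time_corr exceeds a "
                "cross_visit_corr entry; the implied covariance is not positive-definite"
            )
        e2 = 1.0 - np.asarray(self.cross_visit_corr) - d2
        if np.any(e2 <= 0):
            raise ValueError(
                "infeasible glucose correlations: cross_visit_corr + "
                "within_curve_corr - shared_time_corr must stay below 1"
            )
        ai2 = self.insulin_cross_visit_corr
        di2 = self.insulin_within_curve_corr - ai2
        ei2 = 1.0 - self.insulin_within_curve_corr
        if di2 < 0 or ei2 <= 0:
            raise ValueError("infeasible insulin correlation structure")
        for k in ("glu_ins_subject_corr", "glu_ins_visit_corr", "age_glucose_corr", "bmi_glucose_corr"):
            if abs(getattr(self, k)) >= 1:
                raise ValueError(f"{k} must lie in (-1, 1)")
        return (
            math.sqrt(a2), np.sqrt(c2), math.sqrt(d2), np.sqrt(e2),
            math.sqrt(ai2), math.sqrt(di2), math.sqrt(ei2),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glucose_medians"] = {k: list(v) for k, v in d["glucose_medians"].items()}
        d["insulin_medians"] = {k: list(v) for k, v in d["insulin_medians"].items()}
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class Cohort:
    """A generated (or loaded) cohort: wide table + provenance.

    ``table`` holds one row per subject with columns ``id, age, bmi_early,
    bmi_late``, ``glu_{visit}_{t}`` / ``ins_{visit}_{t}`` for visit in
    {w14, w30, y5} and t in {0, 30, 60, 90, 120} (mmol/L and mU/L), and
    outcome columns ``lga`` and ``prediab_5y`` (empty until
    :func:`attach_outcomes` runs). Missing values are ``NaN``.
    """

    table: pd.DataFrame
    params: GeneratorParams | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, provenance: str = "loaded") -> "Cohort":
        table = pd.read_csv(path)
        if "id" not in table.columns:
            raise ValueError("cohort CSV must have an 'id' column")
        if table["id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        return cls(table=table, params=None, provenance=provenance)


def _columns() -> list[str]:
    cols = ["id", "age", "bmi_early", "bmi_late"]
    for series in ("glu", "ins"):
        for visit in VISITS:
            cols += [f"{series}_{visit}_{t}" for t in TIMEPOINTS]
    cols += ["lga", "prediab_5y"]
    return cols


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Draw OGTT curves and demographics for ``params.n_subjects`` women.

    Glucose and insulin at the two pregnancy visits come from one joint
    log-normal across the 10 glucose + 10 insulin coordinates per subject,
    assembled from a latent factor model that realizes the requested
    correlation blocks exactly. Follow-up columns and outcome flags stay
    ``NaN`` until :func:`attach_outcomes`.
    """
    n = params.n_subjects
    nt = len(TIMEPOINTS)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[0])
    a_g, c_t, d_g, e_t, a_i, d_i, e_i = params._loadings()

    # latent factors (documented draw order)
    u_g = rng.standard_normal(n)                     # subject-level glycemia
    w_t = rng.standard_normal((n, nt))               # per-timepoint, shared across visits
    h_g = rng.standard_normal((n, 2))                # per-visit glucose shift
    eps_g = rng.standard_normal((n, 2, nt))
    u_i_raw = rng.standard_normal(n)
    h_i_raw = rng.standard_normal((n, 2))
    eps_i = rng.standard_normal((n, 2, nt))

    kappa = params.glu_ins_subject_corr
    lam = params.glu_ins_visit_corr
    u_i = kappa * u_g + math.sqrt(1 - kappa**2) * u_i_raw
    h_i = lam * h_g + math.sqrt(1 - lam**2) * h_i_raw

    z_g = (
        a_g * u_g[:, None, None]
        + c_t[None, None, :] * w_t[:, None, :]
        + d_g * h_g[:, :, None]
        + e_t[None, None, :] * eps_g
    )
    z_i = a_i * u_i[:, None, None] + d_i * h_i[:, :, None] + e_i * eps_i

    data = {"id": [f"S{i + 1:06d}" for i in range(n)]}
    sd_g = np.asarray(params.glucose_log_sd)
    sd_i = np.asarray(params.insulin_log_sd)
    for vi, visit in enumerate(("w14", "w30")):
        mg = np.log(params.glucose_medians[visit])
        mi = np.log(params.insulin_medians[visit])
        glu = np.exp(mg[None, :] + sd_g[None, :] * z_g[:, vi, :])
        ins = np.exp(mi[None, :] + sd_i[None, :] * z_i[:, vi, :])
        for ti, t in enumerate(TIMEPOINTS):
            data[f"glu_{visit}_{t}"] = glu[:, ti]
            data[f"ins_{visit}_{t}"] = ins[:, ti]

    # demographics, correlated with subject-level glycemia
    rho_a, rho_b = params.age_glucose_corr, params.bmi_glucose_corr
    age = params.age_mean + params.age_sd * (
        rho_a * u_g + math.sqrt(1 - rho_a**2) * rng.standard_normal(n)
    )
    z_bmi = rho_b * u_g + math.sqrt(1 - rho_b**2) * rng.standard_normal(n)
    bmi_early = np.exp(np.log(params.bmi_log_median_early) + params.bmi_log_sd * z_bmi)
    bmi_late = np.exp(np.log(params.bmi_log_median_late) + params.bmi_log_sd * z_bmi)
    data["age"] = age
    data["bmi_early"] = bmi_early
    data["bmi_late"] = bmi_late

    table = pd.DataFrame(data)
    for visit in ("y5",):
        for series in ("glu", "ins"):
            for t in TIMEPOINTS:
                table[f"{series}_{visit}_{t}"] = np.nan
    table["lga"] = np.nan
    table["prediab_5y"] = np.nan

    if params.missing_early_fraction > 0:
        missing = rng.random(n) < params.missing_early_fraction
        for series in ("glu", "ins"):
            for t in TIMEPOINTS:
                table.loc[missing, f"{series}_w14_{t}"] = np.nan

    table = table[_columns()]
    return Cohort(table=table, params=params, provenance=f"synthetic seed={params.seed}")


def _solve_intercept(z: np.ndarray, slope: float, target_rate: float) -> float:
    """Intercept making the mean logistic probability hit ``target_rate``."""
    def gap(alpha):
        return expit(alpha + slope * z).mean() - target_rate
    return brentq(gap, -30.0, 30.0)


def _truncated_lognormal(rng, median, log_sd, low, high, size):
    """Log-normal draw restricted to [low, high] (either may be None)."""
    mu = math.log(median)
    if log_sd == 0:
        val = min(max(median, low or median), high or median)
        return np.full(size, val)
    a = -np.inf if low is None else (math.log(low) - mu) / log_sd
    b = np.inf if high is None else (math.log(high) - mu) / log_sd
    pa, pb = ndtr(a), ndtr(b)
    u = rng.random(size)
    z = ndtri(pa + u * (pb - pa))
    return np.exp(mu + log_sd * z)


def attach_outcomes(cohort: Cohort, params: GeneratorParams | None = None) -> Cohort:
    """Plant LGA and 5-year pre-diabetes outcomes on a generated cohort.

    LGA is Bernoulli with logit linear in standardized late-visit AUC
    glucose (slope ``lga_log_or_per_sd_aucglu``); the intercept is solved
    so the marginal rate equals ``lga_base_rate``. Pre-diabetes at the
    follow-up visit is Bernoulli with logit linear in standardized log
    beta-cell function (ISSI-2) at 14-16 weeks (slope
    ``prediab_log_or_per_sd_betacell``, default ln 0.34 per SD). The
    follow-up fasting and 2 h glucose are then drawn from truncated
    log-normals consistent with each subject's flag, so that applying the
    ADA pre-diabetes rule to the generated y5 OGTT reproduces the flag.

    Subjects whose early OGTT is missing cannot enter the pre-diabetes
    model; they are excluded (flag left missing) and counted in the
    returned cohort's provenance string.
    """
    params = params or cohort.params
    if params is None:
        raise ValueError("generator params required to attach outcomes")
    table = cohort.table.copy()
    n = len(table)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(2)[1])

    # --- LGA from standardized late-visit AUC glucose -------------------
    panel_late = panel_frame(table, "w30")
    auc = panel_late["auc_glucose_w30"].to_numpy()
    if np.isnan(auc).all():
        raise ValueError("late-visit OGTT required to attach LGA outcomes")
    z_auc = (auc - np.nanmean(auc)) / np.nanstd(auc)
    alpha = _solve_intercept(z_auc[~np.isnan(z_auc)], params.lga_log_or_per_sd_aucglu,
                             params.lga_base_rate)
    p_lga = expit(alpha + params.lga_log_or_per_sd_aucglu * z_auc)
    lga_draw = rng.random(n)
    table["lga"] = np.where(np.isnan(p_lga), np.nan, (lga_draw < p_lga).astype(float))

    # --- follow-up subsample --------------------------------------------
    follow = rng.random(n) < params.follow_up_fraction

    # --- pre-diabetes from standardized log beta-cell function ----------
    panel_early = panel_frame(table, "w14")
    issi = panel_early["issi2_w14"].to_numpy()
    eligible = follow & np.isfinite(issi)
    n_excluded = int(follow.sum() - eligible.sum())
    log_issi = np.where(eligible, np.log(np.where(eligible, issi, 1.0)), np.nan)
    mu, sd = np.nanmean(log_issi), np.nanstd(log_issi)
    if not sd > 0:
        raise ValueError("beta-cell function is degenerate; cannot standardize")
    z_beta = (log_issi - mu) / sd
    slope = params.prediab_log_or_per_sd_betacell
    alpha_p = _solve_intercept(z_beta[eligible], slope, params.prediab_base_rate)
    p_pre = expit(alpha_p + slope * z_beta)
    pre_draw = rng.random(n)
    prediab = np.where(eligible, (pre_draw < p_pre).astype(float), np.nan)
    table["prediab_5y"] = prediab

    # --- follow-up OGTT consistent with the flag ------------------------
    med = params.y5_glucose_medians
    sd5 = params.y5_glucose_log_sd
    idx_follow = np.flatnonzero(follow)
    nf = idx_follow.size
    if nf:
        glu5 = np.empty((nf, len(TIMEPOINTS)))
        for ti in (1, 2, 3):  # mid-curve samples are unconstrained
            glu5[:, ti] = _truncated_lognormal(rng, med[ti], sd5[ti], None, None, nf)
        flag = prediab[idx_follow] == 1.0
        trigger = rng.random(nf)  # which component realizes pre-diabetes
        via_fasting = flag & (trigger < 0.5)
        via_2h = flag & ~via_fasting
        both = flag & (rng.random(nf) < 0.25)
        fast = _truncated_lognormal(rng, med[0], sd5[0], None, 5.6, nf)
        two_h = _truncated_lognormal(rng, med[4], sd5[4], None, 7.8, nf)
        hi_fast = _truncated_lognormal(rng, med[0] * 1.18, sd5[0], 5.6, 6.9, nf)
        hi_two = _truncated_lognormal(rng, med[4] * 1.25, sd5[4], 7.8, 11.0, nf)
        fast = np.where(via_fasting | both, hi_fast, fast)
        two_h = np.where(via_2h | both, hi_two, two_h)
        glu5[:, 0] = fast
        glu5[:, 4] = two_h
        ins5_fast = _truncated_lognormal(
            rng, params.y5_fasting_insulin_median, params.y5_fasting_insulin_log_sd,
            None, None, nf,
        )
        for ti, t in enumerate(TIMEPOINTS):
            col = table.columns.get_loc(f"glu_y5_{t}")
            table.iloc[idx_follow, col] = glu5[:, ti]
        table.iloc[idx_follow, table.columns.get_loc("ins_y5_0")] = ins5_fast

    prov = cohort.provenance + f" outcomes(excluded_incomplete={n_excluded})"
    return Cohort(table=table, params=params, provenance=prov)
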