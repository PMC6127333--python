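"""Per-SD logistic prediction of 5-year postpartum pre-diabetes.

Beta-cell function (ISSI-2) is log-transformed (natural log; the per-SD
odds ratio is base-invariant) and standardized within the analysis sample,
so each logistic coefficient exponentiates to an odds ratio per SD change.
Inference is Wald throughout: 95% CI = exp(coef +/- 1.96 se), per-predictor
Wald statistic (coef/se)^2, and a joint Wald chi-square over all
non-intercept terms as the model's combined score. Collinearity between
the first- and third-trimester exposures is reported as tolerance
(1 - R^2 of one predictor regressed on the others) and VIF = 1/tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with per-SD odds ratios."""

    names: tuple
    coef: tuple
    se: tuple
    odds_ratios: tuple
    ci_low: tuple
    ci_high: tuple
    wald: tuple           # per-predictor (coef/se)^2
    p_values: tuple
    wald_total: float     # joint Wald chi-square over non-intercept terms
    log_likelihood: float
    n: int
    converged: bool
    separation: bool = False

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "log_likelihood": self.log_likelihood,
            "wald_total": self.wald_total,
            "converged": self.converged,
            "separation": self.separation,
            "predictors": {
                name: {
                    "coef": c, "se": s, "or": o,
                    "ci": [lo, hi], "wald": w, "p": p,
                }
                for name, c, s, o, lo, hi, w, p in zip(
                    self.names, self.coef, self.se, self.odds_ratios,
                    self.ci_low, self.ci_high, self.wald, self.p_values,
                )
            },
        }


@dataclass(frozen=True)
class CollinearityReport:
    predictors: tuple
    tolerance: tuple
    vif: tuple

    def __post_init__(self) -> None:
        for t, v in zip(self.tolerance, self.vif):
            if np.isfinite(t) and np.isfinite(v) and abs(t * v - 1.0) > 1e-9:
                raise ValueError("VIF must equal 1/tolerance")


def standardize_log(values) -> np.ndarray:
    """Natural log then z-score (population SD) of a positive marker.

    Missing values pass through as ``nan`` and are excluded from the mean
    and SD; all-equal inputs have zero SD and are rejected.
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if finite.size == 0:
        raise ValueError("no defined values to standardize")
    if np.any(finite <= 0):
        raise ValueError("standardize_log requires strictly positive values")
    logged = np.log(v)
    mu = np.nanmean(logged)
    sd = np.nanstd(logged)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (logged - mu) / sd


def _separation_fit(names, n) -> LogisticFit:
    nan = tuple(float("nan") for _ in names)
    return LogisticFit(
        names=tuple(names), coef=nan, se=nan, odds_ratios=nan,
        ci_low=nan, ci_high=nan, wald=nan, p_values=nan,
        wald_total=float("nan"), log_likelihood=float("nan"),
        n=n, converged=False, separation=True,
    )


def fit_logistic(design, outcome, names=None) -> LogisticFit:
    """Fit a logistic regression by maximum likelihood (Newton/IRLS).

    Parameters
    ----------
    design : array-like, shape (n,) or (n, p)
        Predictor column(s); an intercept is added internally and is not
        reported among the predictors.
    outcome : array-like of {0, 1}
        Binary outcome; both classes must be present.
    names : sequence of str, optional
        Predictor names (defaults to x1..xp).

    Notes
    -----
    Perfectly separated data are flagged (``separation=True``) and carry
    no estimates rather than diverging coefficients.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    X, y = X[keep], y[keep]
    n, p = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    if len(set(np.unique(y)) - {0.0, 1.0}) > 0:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    if n <= p + 1:
        raise ValueError("need more observations than parameters")

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            return _separation_fit(names, n)
    coef = res.params[1:]
    se = res.bse[1:]
    if not np.all(np.isfinite(se)) or np.any(np.abs(coef) > 25):
        return _separation_fit(names, n)

    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        wald = (coef / se) ** 2
        pvals = stats.chi2.sf(wald, df=1)
        ors = np.exp(coef)
        ci_lo = np.exp(coef - z * se)
        ci_hi = np.exp(coef + z * se)
    # joint Wald over non-intercept terms
    cov = np.asarray(res.cov_params())[1:, 1:]
    try:
        wald_total = float(coef @ np.linalg.solve(cov, coef))
    except np.linalg.LinAlgError:
        wald_total = float("nan")
    return LogisticFit(
        names=tuple(names),
        coef=tuple(coef),
        se=tuple(se),
        odds_ratios=tuple(ors),
        ci_low=tuple(ci_lo),
        ci_high=tuple(ci_hi),
        wald=tuple(wald),
        p_values=tuple(pvals),
        wald_total=wald_total,
        log_likelihood=float(res.llf),
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def collinearity(design, names=None) -> CollinearityReport:
    """Tolerance and VIF per predictor from auxiliary linear regressions."""
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    tol, vif = [], []
    for j in range(p):
        if p == 1:
            tol.append(1.0)
            vif.append(1.0)
            continue
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        t = max(1.0 - r2, 0.0)
        tol.append(t)
        vif.append(1.0 / t if t > 0 else float("inf"))
    return CollinearityReport(tuple(names), tuple(tol), tuple(vif))


def joint_and_interaction_models(betacell_w14, betacell_w30, gdm, outcome) -> dict:
    """The full second-study model battery.

    Fits, on aligned per-subject columns (standardized log beta-cell
    function at each pregnancy visit, a GDM flag and the 5-year
    pre-diabetes outcome):

    a. each beta-cell exposure alone,
    b. both exposures jointly (with a collinearity report),
    c. early beta-cell function plus GDM,
    d. the same plus their interaction.

    Returns a dict with keys ``w14_alone, w30_alone, joint, betacell_gdm,
    interaction`` (each a :class:`LogisticFit`) and ``collinearity``.
    """
    b14 = np.asarray(betacell_w14, dtype=float)
    b30 = np.asarray(betacell_w30, dtype=float)
    from ogtt_screen.accuracy import _as_flag_array

    g = _as_flag_array(gdm)
    y = _as_flag_array(outcome)
    keep = ~(np.isnan(b14) | np.isnan(b30) | np.isnan(g) | np.isnan(y))
    b14, b30, g, y = b14[keep], b30[keep], g[keep], y[keep]

    out = {
        "w14_alone": fit_logistic(b14, y, ["betacell_w14"]),
        "w30_alone": fit_logistic(b30, y, ["betacell_w30"]),
        "joint": fit_logistic(
            np.column_stack([b14, b30]), y, ["betacell_w14", "betacell_w30"]
        ),
        "betacell_gdm": fit_logistic(
            np.column_stack([b14, g]), y, ["betacell_w14", "gdm"]
        ),
        "interaction": fit_logistic(
            np.column_stack([b14, g, b14 * g]), y,
            ["betacell_w14", "gdm", "betacell_w14:gdm"],
        ),
        "collinearity": collinearity(
            np.column_stack([b14, b30]), ["betacell_w14", "betacell_w30"]
        ),
    }
    return out
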