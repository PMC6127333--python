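# Methods

`ogtt_screen` evaluates how well a 75 g oral glucose tolerance test (OGTT)
taken early in pregnancy (weeks 14–16) predicts (i) a later gestational
diabetes (GDM) diagnosis at weeks 30–32, (ii) a large-for-gestational-age
(LGA) birth, and (iii) pre-diabetes five years postpartum. Because no
individual-level data from such cohorts is publicly deposited, the package
ships a synthetic cohort generator calibrated to published summary
statistics; every analysis stage is exercised against cohorts whose
distributional structure is known and planted.

## Synthetic cohort model

### Joint log-normal biomarker model

Per subject, glucose and insulin at the five OGTT timepoints
(0/30/60/90/120 min) of the two pregnancy visits are jointly log-normal:
20 coordinates `log X_{v,t} = log m_{v,t} + σ_t z_{v,t}` with natural-scale
medians `m` and log-scale SDs `σ`. Log-normality guarantees positivity and
reproduces the right-skewed median (IQR) summaries reported for these
markers.

The standardized residuals `z` follow a latent factor decomposition. For
glucose:

    z_{v,t} = a·u + c_t·w_t + d·h_v + e_t·ε_{v,t}

with independent standard-normal factors: `u` (subject-level glycemia,
shared by everything), `w_t` (timepoint-specific, shared across visits),
`h_v` (visit-specific) and idiosyncratic noise. Squared loadings are solved
from three interpretable correlation parameters:

* `shared_time_corr = a²` — cross-visit, cross-timepoint correlation
  (default 0.40);
* `within_curve_corr = a² + d²` — correlation between timepoints of one
  visit (default 0.60);
* `cross_visit_corr[t] = a² + c_t²` — same-timepoint correlation between
  visits, defaults (0.54, 0.48, 0.54, 0.58, 0.50), the published
  fasting/post-load correlations between the 14–16 and 30–32 week OGTTs.

Insulin uses the same construction without the timepoint factor; its
subject and visit factors are correlated with the glucose factors
(`glu_ins_subject_corr = 0.75`, `glu_ins_visit_corr = 0.40`), producing the
expected positive glucose–insulin coupling (higher HOMA-IR and AUC insulin
in hyperglycemic subjects).

This factor construction is positive-definite *by construction* and
realizes the requested correlations exactly, so no nearest-PD repair step
is ever needed; parameter combinations that would imply an infeasible
(non-PD) covariance — e.g. a cross-visit correlation below the shared
cross-timepoint floor — are rejected with a diagnostic instead of being
silently repaired. Note the planted correlations live on the log scale;
raw-scale Pearson correlations are attenuated by strictly less than 0.01
at the default SDs.

### Calibration of the defaults

The default medians and SDs were chosen once, by matching published
summary statistics of a low-risk Scandinavian pregnancy cohort
(N = 1031), and then frozen:

* fasting-glucose medians 4.60 (early) / 4.75 mmol/L (late) and log-SD
  0.075 place the emergent GDM prevalences near the published 13.4%
  (WHO1999), 24.5% (IADPSG2010), 24.8% (WHO2013) and 9.2% (Norway2017);
  GDM is *emergent* from the glucose distributions, never a planted label;
* the per-visit curve shapes give median AUC glucose 21.1 (early) and
  26.5 (late) in 30-min units;
* insulin medians are pinned by the published Matsuda medians (210 early,
  114 late) and HOMA-IR medians (0.75 / 1.12): fasting insulin medians
  3.65 / 5.30 mU/L and mean insulin ≈ 26 / 48 mU/L; insulin log-SD 0.55
  reproduces the Matsuda IQR (≈149–297 early).

One published table row cannot be satisfied simultaneously with the rest:
an AUC insulin median of ~810 in the same 30-min units would contradict
the Matsuda and HOMA-IR medians under the printed index formulas (it
implies mean insulin ≈ 200 mU/L where Matsuda 210 requires ≈ 26). We
treat this as a unit inconsistency in the source table and calibrate to
Matsuda/HOMA-IR/AUC-glucose; the emergent beta-cell-function (ISSI-2)
medians then land within 6% of the published 1140 / 927, supporting that
reading.

The published 8.2% / 36% / 35% early→late rises of fasting / 60-min /
120-min glucose were measured *within diagnosed GDM women*; as population
median shifts they would contradict the printed early-pregnancy
prevalences. The defaults plant modest population shifts (fasting ×1.03,
post-load ×1.2–1.35); conditioning on a late GDM diagnosis then reproduces
elevations of the published magnitude through selection alone.

The within-curve correlation is not published anywhere we know of; 0.60
(glucose) / 0.65 (insulin) are free calibration constants chosen to give
OGTT curves of realistic smoothness and to keep the multi-component
criteria's positive-set overlap (and hence the IADPSG/WHO2013 prevalence
gap over WHO1999) plausible.

### Outcome models

* **LGA** — Bernoulli with logit linear in standardized late-visit AUC
  glucose, slope 0.35 per SD; the intercept is solved numerically
  (Brent's method on the realized scores) so the marginal rate equals
  `lga_base_rate = 13.8%`. The slope reproduces the published ~1.9-fold
  LGA enrichment in WHO1999-diagnosed GDM.
* **Pre-diabetes (5 y)** — Bernoulli with logit linear in standardized
  log ISSI-2 at 14–16 weeks, slope `ln 0.34` per SD (the published
  protective per-SD odds ratio), marginal rate 20/300. The follow-up
  fasting and 2 h glucose are then drawn from truncated log-normals
  consistent with each subject's flag, so applying the ADA pre-diabetes
  rule to the generated follow-up OGTT reproduces the flag exactly.

Every subject has a follow-up visit by default (`follow_up_fraction = 1`);
the source study's 300/1031 follow-up loss is reproducible by lowering
this fraction. An optional `missing_early_fraction` removes the early
OGTT for a random subset, emulating the shifting denominators of real
cohorts; such subjects are excluded (and counted) wherever the early
visit is required.

Determinism: all draws flow from two generator streams spawned from the
single seed (curves/demographics, then outcomes) in a fixed documented
order, so identical parameters give byte-identical cohorts.

### What the generator does and does not emulate

It reproduces marginal medians/IQRs, cross-visit and within-curve
correlation structure, emergent criterion prevalences and the planted
outcome effects. It does **not** model pregnancy physiology
mechanistically: no gestational trends within a visit window, no
covariate effects beyond age/BMI correlations with glycemia, no
parity/smoking/preeclampsia effects, no assay error structure, and
glucose curves have no subject-specific shape classes. Passing tests
therefore demonstrate the *machinery* is correct under the study's
distributional assumptions — not that the screening conclusions transfer
to any particular real population.

## Metabolic indices

With glucose in mmol/L and insulin in mU/L:

* `Matsuda = 10000 / √(G₀ · I₀ · Ḡ · Ī)`, the means being unweighted
  arithmetic means of the five timepoints (the validated convention for
  five-sample OGTTs);
* `HOMA-IR = I₀ · G₀ / 22.5`;
* `ISSI-2 = (AUC_ins / AUC_glu) · Matsuda` (beta-cell function);
* `IGI = (I₃₀ − I₀) / (G₃₀ − G₀)`; a zero glucose increment leaves IGI
  undefined (`NaN`), the subject is retained for the other indices.

AUCs use the trapezoidal rule over 0–120 min. **Time unit:** adjacent
standard timepoints are one unit (30 min) apart, so a flat curve at `c`
has AUC `4c` and AUC glucose ≈ 4 × mean glucose — the convention that
matches the magnitudes of the published summary table (which never states
the unit). `unit="min"`/`"hour"` are offered for interoperability. A flat
curve obeys `Matsuda × HOMA-IR = 10000/22.5` exactly, which the tests use
as an identity check.

## Diagnostic criteria engine

Thresholds (mmol/L, 75 g OGTT): WHO1999 — 2 h ≥ 7.8; IADPSG2010 —
fasting 5.1–6.9 or 1 h ≥ 10.0 or 2 h 8.5–11.0, plus early-pregnancy
fasting 5.1–6.9; WHO2013 — same OGTT thresholds at any time in pregnancy;
Norway2017 — fasting ≥ 5.3 or 2 h ≥ 9.0; ADA pre-diabetes — fasting
5.6–6.9 or 2 h 7.8–11.0 at follow-up.

Conventions:

* all comparisons are inclusive at the printed lower bound and applied to
  stored values without rounding;
* printed upper bounds (6.9, 11.0) mark the GDM/overt-diabetes boundary:
  values above still classify positive but set `overt_flag`, reported
  separately. A hard upper-bound exclusion would break two structural
  invariants (raising glucose could turn a positive negative, and
  WHO1999 2 h ≥ 8.5 could fail to imply WHO2013 positivity), and such
  subjects are excluded from these cohorts at recruitment anyway;
* the 1 h threshold applies to the 60-min sample only;
* reference GDM labels use the 30–32 week OGTT, extended by each
  criterion's own timing rule (WHO2013: either pregnancy OGTT; IADPSG2010:
  early fasting shortcut); early-screen labels use the 14–16 week OGTT
  alone. A subject missing a required sample is undefined (`<NA>`), never
  silently negative — except that a late-visit-evaluable negative stays
  negative under WHO2013 when only the early visit is missing.

## Sweep procedures

**Scaled-cutoff grid.** Step `k` multiplies the fasting lower bound by
`1 − 0.01k` and the 60-/120-min bounds by `1 − 0.04k`, coupled (one `k`
per step, default 12 steps, i.e. up to 12%/48% decreases). The 1:4
coupling compensates the smaller gestational rise of fasting glucose.
Overt upper bounds and the early-FPG shortcut never scale; WHO1999 scales
only its single 2 h component. Because thresholds only fall, the positive
sets are nested and sensitivity/specificity are exactly monotone along
the grid — a structural property the tests assert on arbitrary cohorts.
Whether the published figure swept the two decrease rates coupled or
independently is not stated; coupled is assumed from its single axis.

**Percentile grid.** Cut-offs at whole-population percentiles
(default 5%-steps, endpoints excluded), linear interpolation between
order statistics, ties broken by `≥` on the cut-off. Risk orientation is
per marker: glucose-like markers flag high values, beta-cell function
flags low values.

**Crossing detection.** Third-order polynomials are fitted by least
squares to sensitivity and specificity versus grid step; the crossing is
the real root of the difference polynomial inside the grid range nearest
the raw sign change, and the reported value is the mean of the two fits
at the root. Profiles with no sign change return no crossing; identical
profiles return mid-grid with a degeneracy flag.

**Risk-factor combination.** The OGTT screen is OR-combined with BMI ≥ 30
and/or age ≥ 35; subjects missing a requested covariate are dropped.

## Accuracy and inference

* 0/0 accuracy ratios are undefined (`NaN`), never 0 or 1.
* Odds ratios: cross-product with Woolf (log-OR normal) 95% CI; +0.5
  continuity correction on all cells iff any cell is zero; two-sided Wald
  p-value. The source's CI method is unstated; Woolf is assumed and the
  method is recorded in the result object.
* ROC AUC = Mann–Whitney concordance with ties at ½ (computed via
  scikit-learn, tested against `scipy.stats.mannwhitneyu`).
* Logistic models: maximum likelihood (statsmodels Newton/IRLS). Beta-cell
  function enters as natural log, standardized with the population SD
  (ddof 0) *within the analysis subsample*, so coefficients exponentiate
  to per-SD odds ratios; base of the log is immaterial per SD. Inference
  is Wald throughout (per-predictor `(β/SE)²`, joint Wald chi-square as
  the model's combined score) to match the reporting style being
  emulated. Perfect separation is flagged, with no estimates, rather than
  returning divergent coefficients. Collinearity: tolerance = 1 − R² of
  each predictor on the others, VIF = 1/tolerance (exact identity).

## Numerical choices and problem sizes

Intercepts of the outcome models are solved with Brent's method on
[−30, 30]; truncated log-normals use inverse-CDF sampling. The test suite
checks calibration at n = 100 000 (correlations ±0.01, medians ±10%),
prevalences at the study size n = 1031 (±3 percentage points), planted-OR
recovery at n = 3000 with 200-replicate CI coverage required to lie in
[0.90, 0.99], and sweep monotonicity on 50 random cohorts of n = 120 —
sizes chosen so the whole suite runs in seconds while keeping Monte-Carlo
noise far below every asserted tolerance.

## Known limitations

* The generator's glucose–insulin coupling is a two-factor shortcut; real
  OGTT curves show richer shape heterogeneity (e.g. 1 h-peak vs
  monotone-rise phenotypes) that affects index behaviour.
* Follow-up OGTT values are generated conditionally on the planted
  pre-diabetes flag rather than from a longitudinal disease model, so 5-y
  glucose is only marginally realistic.
* The early/late visit pair shares one per-timepoint SD; gestational
  variance inflation is not modelled.
* Woolf CIs and Wald tests are approximations that degrade in the small
  cell counts a 300-subject follow-up with 20 events produces; exact
  intervals are out of scope.
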