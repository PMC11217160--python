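# Methods

`cemdrift` monitors temporal performance drift of in-hospital mortality
risk models for adult cardiac surgery. This note documents the models and
procedures it implements, the defaults and why they were chosen, what the
synthetic registry generator does and does not emulate, and the package's
numerical conventions.

## The consensus metric (CEM)

For a prediction set — per-patient predicted mortality probabilities
$p_i$ with binary outcomes $y_i$ — five component metrics are computed:

* **AUC**, via the Mann–Whitney U statistic with midrank tie handling
  (identical to the trapezoidal ROC area);
* **F1** on the death class at a binarisation threshold $t$:
  $2\,\mathrm{TP} / (2\,\mathrm{TP} + \mathrm{FP} + \mathrm{FN})$, defined
  as 0 when the denominator vanishes;
* **1 − ECE** ("adjusted ECE"), where
  $\mathrm{ECE} = \sum_b \frac{n_b}{N}\,|\bar p_b - \bar y_b|$
  over equal-width probability bins (default 10), empty bins contributing 0;
* **1 − Brier** ("adjusted Brier"),
  $1 - \frac{1}{N}\sum_i (p_i - y_i)^2$, without a prevalence
  normalisation term;
* **overall net benefit**: at decision threshold $p_t$, with confusion
  counts at cutoff $p_t$ (predicted positive when $p_i \ge p_t$),

  $\mathrm{NB}_{\text{treated}} = \frac{\mathrm{TP}}{N} - \frac{\mathrm{FP}}{N}\,\frac{p_t}{1-p_t},
  \qquad
  \mathrm{NB}_{\text{untreated}} = \frac{\mathrm{TN}}{N} - \frac{\mathrm{FN}}{N}\,\frac{1-p_t}{p_t},$

  and the overall value is the *arithmetic* mean of
  $\mathrm{NB}_{\text{treated}} + \mathrm{NB}_{\text{untreated}}$ over the
  threshold grid (default 0.01–0.99 in steps of 0.01). Arithmetic rather
  than geometric, because per-threshold net benefit can be negative.

The **clinical effectiveness metric** is the geometric mean of the five
components,
$\mathrm{CEM} = (\prod_{k=1}^{5} c_k)^{1/5}$.
If any component is non-positive the geometric mean is undefined; the
package returns NaN with a diagnostic warning naming the offending
components rather than silently clamping. Because the geometric mean is
bounded by the arithmetic mean (AM–GM) and strictly increasing in each
component, CEM gives a single consensus ranking while preserving
sensitivity to every component.

### F1 threshold at low prevalence

The F1 binarisation threshold defaults to 0.5 in the metric function and
is always recorded in outputs. At a realistic 2.76% mortality prevalence,
however, a calibrated model almost never emits probabilities above 0.5, so
the 0.5 cutoff predicts zero deaths, F1 is identically 0 and CEM is
undefined. The pipeline therefore resolves its F1 threshold to the
training-window outcome prevalence unless one is configured explicitly;
the resolved value is written into the run report. This is the standard
decision-threshold choice for heavily imbalanced calibrated classifiers.

## Bootstrap uncertainty and pairing

Metric uncertainty comes from resampling patients with replacement
(default B = 1000; desk-scale analyses in the tests use 40–100). Per
metric, the point estimate is the geometric mean across valid resamples
and the 95% CI the 2.5/97.5 percentiles. Resamples in which only one
outcome class survives get NaN metrics and are counted, not hidden. When a
metric has non-positive resample values (possible for net benefit), its
point estimate falls back to the arithmetic mean and the metric is listed
in `arithmetic_fallback`.

Resample index streams are a pure function of (seed, n, B) — and of the
month index for monthly series — so different models evaluated on the same
cohort slice with the same seed share resamples. All paired comparison
tests rely on this contract; unpaired input is rejected.

Bootstrap resampling is unstratified by default (stratified available):
the observed class counts are themselves part of the sampling uncertainty
a monthly registry slice carries.

## Risk models and validation protocol

Five families are trained on the 18 standardized EuroSCORE II
preoperative variables: logistic regression, random forest, XGBoost, a
class-weighted RBF SVM, and a single-hidden-layer MLP. Hyperparameters
are chosen by stratified 5-fold cross-validation on the training window,
maximising mean fold CEM (AUC selectable), and the final model is refit on
the full training window. The search grids are small, documented
desk-scale defaults (tree depth {3,4,6}, learning rate {0.05,0.1}, 500
forest trees, SVM C {0.1,1,10}, hidden layer {16,32} with early
stopping); they are stand-ins chosen for reproducibility at workstation
scale, not tuned-to-data values.

The weighted SVM applies class weights $w_c = 0.5 / \Pr(c)$ — the
positive-class weight is inverse prevalence — and Platt-style sigmoid
calibration so that, like every other family, it emits probabilities
rather than scores. XGBoost receives the equivalent `scale_pos_weight`.

The EuroSCORE II baseline evaluates the published 18-item logistic model
with its original constant (−5.324537) and coefficients, shipped as a
versioned constant table; it is never refitted. The age term contributes
one unit up to age 60 and one further unit per year beyond.

## Preprocessing

Cleaning is deterministic: missing categorical/ordinal risk factors are
set to the baseline level (risk factor absent), missing age is imputed as
the median age of records sharing its calendar year, records with missing
outcome are dropped and counted, and values outside declared ranges are
clipped — each action tallied in a cleaning report. Standardization
(mean/SD with the sample n−1 SD) is fitted on the training window only and
applied unchanged to the holdout window; binary flags pass through by
default (switchable) since centring a 0/1 indicator changes nothing a
downstream model needs and hurts interpretability. Zero-SD columns are
flagged and passed through unscaled.

The temporal split sends records strictly before the boundary date
(default 2017-01-01) to the training window and the rest to the holdout.

## Drift analysis

For each model, each metric is bootstrapped per holdout month and the
per-month *point estimates* are regressed on the month index (0 = first
holdout month) by OLS. Residual normality (Shapiro–Wilk) and
homoscedasticity (Breusch–Pagan) are checked at α = 0.05; if either
fails, the fit switches to the seasonal Kendall test with Sen slope
(seasons = calendar months), and the method used is recorded. A
noiseless series keeps the linear method with diagnostics skipped; a
constant series reports slope 0 with p = 1.

The comparison batteries follow standard practice for paired bootstrap
distributions: repeated-measures one-way ANOVA, Bonferroni-corrected
one-tailed paired t tests, and a Dunnett-style many-to-one comparison
against a control model for the whole-holdout baseline; Kruskal–Wallis,
Bonferroni-corrected paired Wilcoxon signed-rank tests and the Dunn post
hoc test within calendar windows; paired Wilcoxon with median differences
between windows. The paired Dunnett comparison computes p-values and
family-wise CIs from the equicoordinate tail of a multivariate t with the
estimated correlation of the paired differences (Bonferroni fallback on
degenerate correlation). The DeLong test on correlated ROC areas uses the
Sun–Xu midrank algorithm.

Projection is linear only: `intercept + slope × month`, with Jan 2017 as
month 0 so Jan 2030 is month 156. Requests to project a seasonal-Kendall
fit raise an error rather than pretending a Sen slope extrapolates.

## Variable-importance drift

For each holdout month, 5-fold nested cross-validation is run on that
month's records alone (the per-month convention; a rolling window is a
caller-side change of slicing): the inner loop selects hyperparameters,
each outer fold contributes the mean absolute per-record attribution of
its held-out records, and the month's importance is the geometric mean of
the five fold values. Attributions are exact tree-path SHAP values from
the boosting library's own `pred_contribs` output for XGBoost; for
non-tree families the model-agnostic fallback is permutation importance
(mean |AUC drop| over shuffles). The backend actually used is recorded in
the output.

Series are smoothed with LOESS (span 0.5 — no published value exists —
with a seeded residual-bootstrap 95% band). The change-month estimator is
the two-segment least-squares step fit (split minimising the residual sum
of squares), reported as the first month after the change. The naive
largest-|first-difference| estimator is available as `method="diff"` but
is not the default: a single-month importance spike produces two large
opposite-signed differences that can out-vote a genuine sustained step,
which we observed directly on synthetic series.

## Dataset composition drift

Per-month category proportions are tracked for selected variables
(default: the top 3 by mean importance). Continuous variables are
pre-binned; the default age grouping is <60 / ≥60 with age exactly 60 in
the upper bin by the half-open convention. Month-to-month change is
scored by total-variation distance
$\tfrac12\sum_c |p_a(c) - p_b(c)| \in [0,1]$ (a true metric on
distributions); Jensen–Shannon divergence is available as an alternative.

## The synthetic registry generator

No patient-level registry data are redistributable, so every downstream
stage is exercised on synthetic cohorts with known ground truth. The
generator emulates the *structure* of a UK national adult cardiac surgery
audit: one record per patient over a 2012–2019 monthly calendar, the 18
EuroSCORE II preoperative variables with marginal category frequencies
matching the published cohort summary, and a binary in-hospital mortality
outcome drawn from a logistic model on the risk factors with overall
prevalence 2.76%.

Key mechanics and choices:

* **Intercept calibration.** The outcome intercept is solved by Brent
  root finding on a fixed 200k-draw Monte Carlo sample of the baseline
  linear predictor so that expected pre-drift mortality equals
  `base_mortality` to 1e-6. An unreachable prevalence raises an error
  naming the achievable range.
* **Default coefficients.** Relative magnitudes echo the published
  EuroSCORE II risk-factor coefficients, scaled up ~1.75× because the
  generator draws risk factors independently: independent features carry
  less joint information than correlated registry data, and the scaling
  restores registry-level oracle discrimination (AUC ≈ 0.83) at the same
  prevalence. Features are independent by default; real registries have
  correlated risk factors, so synthetic cohorts understate risk
  concentration in multimorbid patients — a stated limitation, with a
  Gaussian-copula hook left as future work.
* **Drift injection.** Covariate drift replaces a feature's category
  distribution (or shifts a continuous mean) over a month interval;
  concept drift adds a delta to a feature's outcome coefficient over an
  interval — mirroring the distinction between dataset drift and
  variable-importance drift. Optional per-feature sinusoidal seasonality
  tilts the first category (or the mean).
* **Stream splitting.** One pseudo-random stream per (month, feature),
  split from the master seed, so editing one feature's schedule leaves
  every other feature's draws byte-identical.
* **Oracle risk.** `ground_truth_risk` returns the exact data-generating
  probability (month-aware under concept drift); a model predicting it is
  calibrated by construction, which anchors the calibration tests.

What passing tests on these cohorts show: the metrics, bootstrap,
trend-detection and importance machinery behave correctly when the truth
is known. What they do not show: performance on real registry data, where
feature correlations, coding errors, hospital-level clustering and
non-logistic outcome structure all exist and none is emulated.

## Problem sizes used by the test-suite simulations

The simulation-based checks run at deliberately desk-scale sizes, chosen
as the package's own defaults for a workstation run: metric-oracle
enumeration over all ≤6-record multisets on a 9-point probability lattice;
calibration at a single 100,000-record month; slope recovery on 100
series of 27 months with noise SD 0.005 (the scale of the published
bootstrap SDs); null behaviour over 200 stationary 27-month cohorts of
200 patients/month at 8% prevalence (high enough that every month carries
both outcome classes at that volume) with B = 100; concept-drift
detection over 50 replicates at the registry's monthly volume
(2500 patients/month, 2.76% prevalence) with the operative-urgency
coefficient zeroed from holdout month 12. The per-month importance
instrument for those replicates is regularised boosting
(120 trees, learning rate 0.1, `min_child_weight` 10, depth 3) — monthly
slices with ~70 deaths need regularisation for stable refits.

## Known limitations

* Independent synthetic features (above); no hospital-level clustering.
* The published study's own hyperparameter grids and NN architecture are
  not public; the defaults here are declared stand-ins.
* CEM is undefined when a component is non-positive (surfaced as NaN,
  never clamped); with very low prevalence and a poor threshold choice
  this happens routinely — see the F1-threshold note.
* The seasonal Kendall fallback reports trend evidence but refuses
  linear projection; only OLS fits extrapolate.
* Bootstrap CIs are percentile; no BCa correction.
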