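# Methods

## Problem and pipeline

The package predicts incident metabolic syndrome (MetS) one year ahead from
four consecutive MetS-free annual exams, and characterizes which indicator
abnormalities carry the risk. The pipeline stages are independent library
modules: guideline labeling (`reference_ranges`), synthetic cohort
generation (`synthetic_cohort`), cleaning (`preprocessing`), window
construction (`cohort_windows`), temporal feature engineering
(`temporal_features`), classifier benchmarking (`prediction`) and
stratified risk statistics (`risk_stats`).

## Diagnostic rule

A person-year is MetS-positive when ≥ 3 of the five guideline conditions
hold, with inclusive thresholds: WC ≥ 90/85 cm (male/female), fasting
glucose ≥ 6.1 mmol/L (or 2-h postprandial glucose ≥ 7.8 when recorded, or a
diagnosed-diabetes history flag), blood pressure SBP ≥ 130 **or** DBP ≥ 85
mmHg (or a diagnosed-hypertension flag), TG ≥ 1.70 mmol/L, HDL-C ≤ 1.04
mmol/L. The blood-pressure clause is read disjunctively (the standard MetS
convention; a conjunctive reading is available via
`MetSCriteria(hypertension_or=False)`), and history flags can be disabled
(`use_history_flags=False`) for strictly measurement-based labeling.
Diagnosis tolerates missing values only when the decision is already
forced; otherwise it raises rather than guessing.

Normal-range limits for the five MetS-component indicators are the
guideline thresholds themselves (inclusive). The other thirteen indicators
carry standard adult reference limits shipped in
`src/metsflow/data/reference_ranges.yaml`; these are configuration, not
measurement, and sites should override them from their own YAML. Each
indicator also carries much wider physician plausibility bounds used only
for outlier screening.

## Synthetic cohort generator

The generator stands in for private hospital data. It emulates:

- **Marginals.** Per-sex mean ± SD of 18 indicators and age. Values are
  drawn from truncated normals whose *truncated* moments are solved to
  match the targets exactly (for male TG, mean 1.65 ± 1.43 with a floor
  near zero, naive truncation would inflate the mean by ≈ 0.34). Ages are
  drawn on [18, 76] so the five-year follow-up stays within the 18–80
  inclusion window. A moment-matched lognormal is available per indicator
  (`log_scale`) for right-skewed markers.
- **Temporal structure.** Each indicator's latent standard-normal process
  decomposes into a stable subject component (variance share
  `subject_effect`, default 0.60 — clinical biomarkers have intra-class
  correlations of roughly 0.4–0.6), an AR(1) component, and transient
  measurement noise (`transient_noise`, default 0.08). The AR coefficient
  is set so the total lag-1 autocorrelation equals `autocorrelation`
  (default 0.85). Values arise by mapping the latent process through the
  marginal quantile function (Gaussian copula), so marginals are exact at
  every year and correlations live on the latent scale.
- **Cross-indicator correlation.** A single latent "metabolic" factor with
  loadings ~0.75/0.8 on adiposity measures, ~0.5 on blood pressure and
  lipids, negative on HDL-C, near zero on haematology. Height, hip and
  weight are emitted so WHR = WC/hip and BMI = weight/height² are exactly
  coherent and can be re-derived during cleaning.
- **Planted deterioration.** A fraction of subjects (`drift_fraction`,
  default 0.3) follow a deteriorating trajectory on the six MetS-component
  indicators (HDL-C downward). Drift probability rises with the subject's
  metabolic factor (`drift_selectivity`, default 3.0): people who progress
  are mostly those already borderline, so their *levels* resemble stable
  borderline controls and the distinguishing signal is the trajectory.
  Deterioration begins at a random onset year (year 2 or 3 of a 5-year
  panel) and proceeds linearly at a per-subject slope
  (`drift_magnitude × U(0.5, 1.5)` latent SDs per year).
- **Incidence calibration.** When `drift_magnitude` is `None` it is
  calibrated by a coarse grid plus bisection on pilot cohorts (two
  averaged replicates of up to 2,500 subjects, full window/labeling
  pipeline) so the realized window-level incidence matches
  `target_incidence` (default 1338/15661 ≈ 0.0854). Incidence is not
  monotone in the magnitude — very fast drifters turn positive during the
  input years and drop out of the windows — hence the grid stage before
  bisection.

What the generator does **not** emulate: real joint distributions beyond a
one-factor structure, seasonal or visit-level effects, informative
missingness, regional or cohort heterogeneity, medication effects, and any
nonlinearity of real metabolic dynamics. Passing tests therefore validate
the pipeline's mechanics and statistical behaviour, not clinical
performance on real data.

## Cleaning protocol

Applied in order: (1) subjects with more than 20 exam records are excluded;
(2) records with age above 80 are dropped, and indicator values outside the
plausibility bounds are blanked cell-wise — blanking rather than record
removal preserves the 5-year continuity the windows need; (3) WHR and BMI
are re-derived where raw anthropometrics exist (nonpositive denominators
yield missing values); (4) features missing in more than 70% of records
are dropped, and remaining gaps are filled per sex with the mean when the
distribution looks normal — Shapiro–Wilk at α = 0.05 on a capped subsample,
with an |skewness| ≤ 1 fallback because the test over-rejects at large n —
else the median. The chain is idempotent, and every report count reconciles
with the emitted table.

## Windows and features

A window is four consecutive exam years with MetS = 0 plus the next year's
diagnosis as `ms_result`; label-year age must be ≥ 18, and age strata are
18–44 / 45–59 / ≥60. By default one (the earliest) window per subject keeps
samples independent for cross-validation; `mode="all"` emits overlapping
windows.

DFF parameters: sigmoid steepness `a = 50`, decay `b = 0.6`. The risk
distance x is the later-year value minus the indicator's limit (reflected
for HDL-C so clinically worse values always get weight > 0.5 — without the
reflection the weighting would suppress exactly the risky HDL-C changes),
divided by a per-indicator `scale_max`. By default `scale_max` is the
maximum |raw distance| observed in the training windows, fitted once and
frozen so the transform is a pure function at predict time; any constant
(e.g. the indicator's maximum plausible value) can be supplied instead. An
interval's x can alternatively be evaluated at the interval midpoint
(`x_at="mid"`), and the decay weights can be renormalized to sum to one
(`renormalize=True`; note b³ + b² + b = 1.176 at b = 0.6, so the literal
three-term sum is the default). The sigmoid output is clamped into the open
interval (0, 1) to keep extreme arguments finite and order-preserving at
the clamp boundary.

Abnormal-state conventions: an original feature is abnormal beyond its
risk-direction limit (inclusive for the guideline thresholds, strict for
the generic reference limits); a DNF is abnormal when strictly positive; a
DFF is abnormal when |g| exceeds the cohort mean of |g| for that indicator
(per-sex means optional). The DNF flag used in prevalence comparisons is
the most recent interval's.

## Classifiers and evaluation

Stratified k-fold CV (default k = 10, shuffled with the seed) — stratified
because ~8.5% positives make unstratified folds unstable. AUC per fold is
computed from out-of-fold predicted probabilities; accuracy, precision,
sensitivity, specificity and F1 from the confusion matrix at a 0.5
probability threshold (configurable). Undefined metrics (zero denominator)
are reported as missing, not zero. Classifiers: XGBoost (150 trees, depth
4, learning rate 0.1, subsample/colsample 0.8, hist method, single
thread), random forest (200 trees, min leaf 2), logistic regression
(standardized), and a stacking ensemble (out-of-fold probabilities of
XGBoost and RF fed to a logistic meta-learner; a hard-voting variant is
included). Hyperparameters are fixed documented defaults with no search.
Feature importances come from the fitted model (gain-based for trees),
normalized to sum to one, ties broken lexicographically for determinism;
the incremental-AUC curve adds features in importance order and reports the
first point where three consecutive additions each gain < 0.002 AUC.

## Stratified odds ratios

`OR = ad/bc` per (feature, sex, age-group) stratum with Woolf log-normal
CIs, exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). A single zero cell receives the
Haldane–Anscombe 0.5 correction on all four cells and is flagged; two or
more zero cells leave the OR missing with a reason, and empty strata are
emitted as missing rows. The exposure year for original-feature ORs is the
most recent input year. ORs are crude (unadjusted) and no multiplicity
correction is applied, matching the analysis design this package
implements.

## Design notes and limitations

- The sigmoid-weighted features are deterministic transforms of the level
  and delta features. On synthetic cohorts whose labels are threshold
  functions of year-5 values, gradient-boosted trees recover most of the
  trend information from the raw multi-year levels, so the measured AUC
  gains of the delta-based feature sets are small (≈ 0.003–0.01 in the
  benchmark example and acceptance run) and lie within the cross-fold SD
  at desk-scale cohort sizes. Larger separations would require either much
  larger cohorts or label dynamics beyond a threshold rule.
- Generator defaults are assumptions, not estimates from the private data:
  within-subject correlation, drift prevalence/onset/selectivity and the
  factor loadings are all configurable and documented in `CohortConfig`.
- The labeling rule, reference limits and plausibility bounds are
  configuration; nothing in the package hard-codes a specific hospital's
  conventions beyond the shipped defaults.
- SHAP export is a lazy hook (`prediction.shap_values`) requiring the
  optional `shap` package; no plotting beyond that hook is provided.
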