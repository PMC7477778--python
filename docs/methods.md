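# Methods

This note documents the statistical models, parameter choices, and
numerical conventions behind `emrfrailty`, and what the synthetic-data
pipeline does and does not demonstrate about real EMR data.

## The problem

A frailty *case definition* is a computable rule over routinely collected
primary-care EMR data that classifies patients as frail or not frail,
validated against a clinician-assigned reference standard: the Rockwood
Clinical Frailty Scale (CFS), an ordinal judgment scale from 1 (very fit)
to 9 (terminally ill). The reference standard dichotomizes at CFS ≥ 5
("mildly frail"); CFS 4 ("vulnerable") counts as not frail. Eligible
patients are 65 or older with a clinic encounter in the 24 months before
the as-of date. The development cohort structure is 52 sentinel physicians
each rating about 15 of their own patients, with roughly 17.7% rated frail.

## Synthetic cohort generator

Real CPCSSN extracts cannot be redistributed, so the generator emulates the
schema and the statistical structure the pipeline needs:

* **Tables.** One demographics table (id, sex, birth year) and nine
  satellite tables keyed by patient id: billing (ICD-9 code + diagnosis
  text), encounter (reason text), encounter diagnosis (ICD-9 + text), exam
  (BMI, systolic BP, waist), labs (creatinine, fasting glucose, hemoglobin,
  TSH), medication (7-character ATC code + name text), referral, risk
  factor (smoking/alcohol/exercise status), and disease-case indicators for
  eight chronic conditions. Dates are ISO-8601 strings inside the
  configured window (default 2015-01-01 to 2016-12-31); record counts per
  patient are Poisson with per-table means (defaults 6 billing, 8
  encounters, 6 encounter diagnoses, 5 medications, 4 labs, 3 exams, 1
  referral — a plausible two-year utilization profile for a 65+ panel;
  every patient gets at least one encounter so the cohort is eligible by
  construction).

* **Frailty mechanism.** Each configured signal feature `j` (an ICD-9
  prefix, an ATC level-2 code, or a free-text token, with a log-odds weight
  `w_j` and exposure base rate `r_j`) gives each patient an independent
  Bernoulli(`r_j`) exposure `x_ij`. The latent liability is
  `L_i = b0 + Σ_j w_j x_ij + u_phys(i) + ε_i` with standard logistic noise
  `ε` and an optional physician random effect `u` (default sd 0: no
  published value exists to calibrate within-physician clustering, so it is
  off unless requested). The intercept `b0` is solved numerically on the
  realized exposures so that the expected frail fraction equals the target
  prevalence (default 0.177). The CFS score is the count of fixed
  thresholds (−3, −2, −1, 0, 1, 2, 3, 4) below `L_i` plus one, so
  `L_i > 0 ⟺ CFS ≥ 5`; this yields a full ordinal scale whose
  dichotomization is exactly the Bernoulli-logistic model on the exposures.

* **Planted records.** Every exposed patient receives one concrete record
  carrying the planted value (e.g. an encounter-diagnosis row with code
  "290", "290.0" or "290.9"); its other fields are drawn from the
  background pools. Background sampling pools *exclude* the planted values,
  so a planted feature's marginal rate and frailty log-odds match the
  liability model instead of being diluted by chance background
  occurrences; without this exclusion the realized odds ratio of a planted
  feature would be systematically attenuated and dependent on the
  background record rates.

* **Default signal set.** Four exposures chosen to emulate the qualitative
  signature reported for frail primary-care patients: dementia coded as
  ICD-9 290 in encounter diagnoses (log-odds 1.8, rate 0.12), diuretics
  (ATC C03; 1.2, 0.20), "vitamins" in medication names (1.0, 0.18), and
  "obstruction" in billing text (0.8, 0.10). The weights are moderate
  single-deficit effects (odds ratios ≈ 2–6); under them the fitted case
  definition reproduces the characteristic low-sensitivity /
  high-specificity outcome of real EMR frailty phenotyping rather than a
  trivially separable cohort.

* **Determinism.** All sampling flows from one `numpy` Generator seeded by
  `SimConfig.seed`; tables are sorted on all columns before emission, so an
  identical configuration reproduces byte-identical CSVs.

What the generator does **not** emulate: longitudinal disease
trajectories, correlated comorbidity structure, realistic free-text beyond
short unigram-bearing fields, missing-data mechanisms, or inter-rater
disagreement in CFS scoring (every patient has exactly one assessment).
Passing tests therefore demonstrate that the *pipeline* recovers signals
of known strength under the stated noise model — not that the case
definition would achieve any particular accuracy on real records.

## Feature extraction

All rules produce presence/absence indicators unless noted:

* ICD-9 codes from billing and encounter diagnoses are truncated to their
  first 3 characters (disease category; V-codes included), one indicator
  per truncated code per source table.
* Free text (billing diagnosis text, encounter reason, encounter-diagnosis
  text, medication name) becomes a unigram term-document matrix: lowercase,
  split on any non-alphanumeric character, numeric tokens kept, no
  stop-word removal, single characters kept.
* ATC codes are truncated to level 2 (therapeutic subgroup, e.g. C03).
* Labs and biometrics are categorized low/normal/high at fixed cut-offs:
  creatinine 53–106 µmol/L, fasting glucose 3.9–6.1 mmol/L, hemoglobin
  135–180 g/L, TSH 0.5–5 mU/L, BMI 22–30, systolic BP 90–140 mmHg. Range
  endpoints belong to "normal" (the only reading consistent with printed
  "< low" / "> high" bounds). Waist has no published cut-off in this
  pipeline's sources; it is dichotomized large/small at the standard
  metabolic-syndrome thresholds, 102 cm (male) / 88 cm (female),
  configurable.
* Per-table aggregates use each patient's reference date (their latest
  encounter; cohort as-of date if they have none): year 1 is the 12 months
  ending at the reference date, year 2 the 12 months before. Counts are of
  *unique* record values. The two-year unique total is categorized at
  "less than 5" / "between 5 and 10" (both endpoints inclusive) /
  "greater than 10" — poly-billing, poly-encounter, polypharmacy. The
  absolute change (year 1 − year 2) and relative change
  (absolute / max(year-2 count, 1), guarding division by zero) are kept
  numeric: they are intrinsically signed quantities and binarizing them
  would destroy the information the aggregate is meant to carry. Age is
  the other numeric feature.
* Missing data encodes as 0 everywhere. Binary features observed in 5 or
  fewer patients are dropped; numeric features are exempt from the filter.
  Features are ordered by family then name, so the matrix is reproducible.

## CHAID

The tree learner is the classic Kass chi-square automatic interaction
detector, restricted to a binary outcome:

* **Split statistic.** Pearson χ² on the 2 × k outcome-by-category table,
  no continuity correction, df = k − 1. Tables with an all-zero row or
  column score (statistic 0, p = 1): a predictor that does not vary inside
  a node is uninformative, not an error.
* **Category merging.** For multi-category predictors, the pair of
  category groups whose 2 × 2 sub-table has the largest p-value is merged
  while that p-value exceeds the merge threshold (set equal to α) and more
  than two groups remain. Binary predictors pass through unchanged. The
  feature matrix is binary by construction — numeric columns (age, change
  features) are dichotomized at their training median before growth — so
  merging matters only when the classifier is used on externally supplied
  categorical data.
* **Multiplicity adjustment.** The best raw p-value at a node is
  multiplied by the number of candidate features examined there (all
  columns, including degenerate ones — a deterministic, conservative
  convention) times the Kass partition coefficient (the number of ways to
  partition c nominal categories into the g merged groups) when merging
  occurred. The node splits on the winner only if the adjusted p ≤ α.
  Ties break toward the larger χ² statistic, then the lexicographically
  first feature name, so fits are reproducible.
* **Stopping.** Maximum height (default 4), minimum node size (default 10;
  no published value, configurable), node purity, or no significant split.
* **Leaves.** A leaf predicts frail when its frail proportion strictly
  exceeds `leaf_rule` (default 0.5). At prediction time a feature absent
  from the supplied matrix reads as 0 (the global missing-as-zero rule);
  category values unseen in training fall into the largest child.

Hyper-parameters follow the published search: α from 0.01 to 0.3 in steps
of 0.03 crossed with heights 2–6, scored by bootstrap out-of-bag
performance. The published chosen value α = 0.12 does not lie on that
printed grid; both the grid and the chosen value are supported as given,
and the default `ChaidClassifier(alpha=0.12, max_height=4)` uses the
chosen pair. Because the original selection was made by visual inspection
of metric plots, the automated search needs an explicit scalar criterion:
the mean out-of-bag Youden index (sensitivity + specificity − 1), with
ties resolved toward the smaller height then smaller α. Bootstrap
replicates default to B = 200 (no published value).

## LASSO baseline

The baseline minimizes the mean logistic deviance plus `λ‖β‖₁` with an
unpenalized intercept, by cyclic coordinate descent where each coordinate
step is a proximal majorization step with curvature bound `‖x_j‖²/(4n)`
(the logistic Hessian is bounded by 1/4). Every update therefore decreases
the objective — the per-iteration objective path is exposed and asserted
monotone in the tests — and convergence is declared on the KKT subgradient
residual (default tolerance 1e-7). Coordinate-wise bounds make the solver
invariant to column scaling, so binary indicators and the numeric age
column coexist without standardization; features are not standardized by
default (binarization already equalizes scale; a flag exists). An
active-set strategy (nonzero coefficients plus current KKT violators per
sweep) keeps full-matrix fits fast.

λ is selected by stratified 10-fold cross-validated held-out deviance over
a user grid, descending with warm starts; exact ties resolve toward the
larger (sparser) penalty. When the baseline is converted to a
classification, probability 0.5 is the cut-off (no published threshold).
The published λ = 0.035 arose from the original real-data fit and is a
procedural anchor only, not a reproduction target.

## Diagnostic-accuracy evaluation

* **Pooling.** k-fold CV (stratified, seeded) predicts each record exactly
  once out-of-fold and pools all predictions into one confusion matrix
  before computing metrics. Pooling (rather than averaging per-fold
  metrics) is what makes the CI denominators equal the full class sizes —
  the convention under which the published intervals are exactly
  reproducible from the published counts.
* **Intervals.** Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV
  and accuracy are each a binomial proportion with its own denominator.
  The default 95% interval is the Wilson score interval with continuity
  correction exactly as R's `prop.test` computes it (including the
  correction cap at |x − n/2|): checked against `prop.test` output to
  1e-9, and it reproduces all five published validation intervals to the
  printed two decimals, which identifies it as the method behind them.
  The exact Clopper-Pearson interval (beta quantiles) is also provided;
  it carries the guaranteed ≥ 95% coverage used in the coverage test.
  Metrics with a zero denominator are reported as undefined, never as 0.
* **Bootstrap tuning.** For each grid point, B resamples with replacement
  are fit and scored on their out-of-bag records (a resample that exhausts
  the data is redrawn); per-metric means and spreads feed the
  height-by-metric tuning curves, and selection maximizes mean Youden.

## Numerical and degenerate-input conventions

* χ² on tables with zero margins → p = 1; empty nodes are errors.
* `b0` is solved by Brent's method on [−30, 30]; a target prevalence
  unreachable on that bracket (pathological weights) raises.
* Aggregate windows are half-open on the left, closed at the reference
  date; a patient with no records contributes zeros everywhere.
* All seeds below 2³¹; derived seeds come from `numpy.random.SeedSequence`
  spawning so that grid order never silently changes downstream draws.

## Known limitations

* The synthetic cohort is exchangeable across patients given exposures;
  real panels cluster by physician and practice EMR. The physician random
  effect is available but uncalibrated.
* Unigram text features cannot represent negation or context ("no memory
  loss" fires "memory"); this mirrors the term-document design it
  implements, not a defect of the tests.
* The real study's printed feature totals and fitted tree depend on real
  CPCSSN data and are not reproducible; the pipeline reports its own
  totals and recovers planted structure instead.
* CHAID here supports binary outcomes only; multi-way splits on continuous
  predictors beyond the median-indicator convention, surrogate splits, and
  post-pruning are out of scope (CHAID pre-stops by significance).
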