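# Methods

## Problem and scope

`negprog` re-implements, end to end, a prognostic analysis of 9-month
negative-symptom outcomes in clinical high-risk (CHR) individuals: binary
outcome labelling from SIPS negative items, leave-site-out (LSO) nested
cross-validation of linear classifiers on clinical and ROI-gyrification
features, stacked combination, posterior balanced-accuracy inference,
cross-validation-ratio (CVR) feature importance, and a two-stage sequential
Bayesian risk stratification with number-needed-to-treat (NNT) estimation.
The original multi-site cohort is not publicly deposited, so the package
ships a synthetic-cohort generator as first-class, tested code; all
simulation studies run on generated data.

## Outcome definitions

A subject has a *moderate/severe* negative-symptom outcome when any of the
SIPS items N1 (social anhedonia), N2 (avolition), N3 (expression of
emotion), N4 (experience of emotions and self) or N6 (occupational
functioning) is rated ≥ 3 at the 9-month follow-up. N5 (ideational
richness) is excluded from predictors and labels, reflecting factor-analytic
evidence that it separates from the other negative items. Global
Functioning Social/Role scores (1–10) dichotomize at ≤ 7 (*impaired*) vs
> 7 (*adequate*). Labelling is complete-case: subjects missing any
follow-up item are dropped from labelled outputs.

## Synthetic cohort generator

One standard-normal latent severity `z` per subject drives every outcome-
relevant quantity:

* **Baseline ordinal items.** Each of N1–N4, N6 (and the carried-but-unused
  N5) is `v = 0.8·z + 0.6·ε` cut into 0..6 by an equal-width grid (step
  0.6). The 0.8 loading yields strongly but imperfectly correlated items,
  as rating scales show.
* **Follow-up severity and items.** `s = (clinical_effect·z + e)/√(1+clinical_effect²)`,
  so `clinical_effect` (default 0.6) is the tunable link between baseline
  presentation and follow-up state. Follow-up items use the same item
  model, but the cut between ratings 2 and 3 is solved numerically
  (Gauss–Hermite quadrature + Brent root finding) so that
  P(any item ≥ 3) equals `target_prevalence` exactly in expectation. The
  binary outcome is then **computed from the items by the labelling rule**,
  never sampled directly — labels and items cannot disagree.
* **Gyrification ROIs.** 68 Desikan–Killiany columns: per-ROI baseline
  levels (uniform 2.0–3.5; the absolute scale is immaterial because
  features are z-scored inside training folds), additive per-(site, ROI)
  offsets with SD `site_sd` (default 0.02), subject noise SD 0.1, and — for
  `n_signal_rois` planted ROIs — a between-class mean shift of
  `roi_effect` within-class SDs (default 0.8) whose per-ROI sign is drawn
  (or pinned via config) and returned in the generator metadata. Observed
  values are multiplied by ICV/mean-ICV so that the pipeline's ICV
  normalization is a meaningful, invertible step; ICV is lognormal around
  1.5×10⁶ mm³ with 8% CV.
* **Functioning scores.** GF Social/Role derive from the same follow-up
  severity (`8 − 1.2·s + 0.8·ε`, clipped to 1..10), so functional-outcome
  generalization is testable without being deterministic.
* **Presets.** `CohortConfig.for_group` matches the emulated study samples:
  CHR n=94 at 40% prevalence, ROP n=96 at 59%, ROD n=97 at 32%, all across
  7 sites.

What the generator does **not** emulate: item-specific factor structure
(volition vs emotion dimensions), missing data, site differences in
prevalence or scanner-specific covariance, longitudinal trajectories beyond
two timepoints, and any vertex-level imaging. Passing recovery tests
therefore demonstrate correctness of the pipeline's statistical machinery on
data satisfying its assumptions — not expected performance on real cohorts.

## Feature views and preprocessing

Two views: the five baseline SIPS-N items and the 68 ROI gyrification
values. Gyrification is normalized for intracranial volume by proportional
division, `roi × reference_icv / icv`, with the reference fixed to the
*training partition's* mean ICV (residualization was considered; division is
the simplest reproducible reading and is scale-equivariant). Features are
z-standardized with training-partition parameters only (population-SD
convention, divisor n); zero-variance features are flagged and scaled by 1.
Ordinal SIPS items are z-scaled like any feature (raw-ordinal mode is
available by passing the matrix directly). No test-set statistic enters any
transform; the leakage tests assert this.

## Nested cross-validation

* **Outer loop:** one fold per site (LSO). A single-class outer training
  set is a hard error; a single-class *inner* training split triggers a
  re-draw of the inner partition with a fresh seed.
* **Inner loop:** stratified k-fold × r repeats (defaults k=5, r=10) on the
  outer-training subjects only, selecting the L2 regularization strength C
  from a log-spaced grid (default 10⁻³…10³) by mean inner balanced
  accuracy. scikit-learn's `RepeatedStratifiedKFold` requires k ≥ 2, so the
  degenerate single-split sanity check uses k=2, r=1 with the `refit`
  ensemble rule.
* **Ensembling:** all k·r inner models at the winning C are retained, each
  with its own ICV reference and scaler; the held-out site's score is the
  mean member decision value (order-invariant). A `refit` rule (one model
  refit on the full outer-training set) is config-switchable, since the
  original software's exact ensembling rule is not public.
* **Classifier family:** L2 logistic regression (default) or linear hinge
  loss (LinearSVC). Class imbalance is handled by inverse-prevalence sample
  weights (on by default). The decision threshold is fixed at 0
  (probability ½); no threshold tuning, matching a single reported
  operating point.
* **Stacking:** meta-features are the base models' out-of-site scores; the
  meta-learner is the same linear family under the same scheme. A
  provenance check (score fold must equal the subject's site) raises a
  leakage error on any in-sample base score.
* **External application:** the grand ensemble (all members of all outer
  folds, each with its stored preprocessing) scores external cohorts;
  scoring subjects from the training cohort is refused in evaluation mode.

## Performance metrics and posterior BAC

Point metrics come from pooled out-of-site confusion counts (one matrix per
model, as a single reported operating point implies): SE, SP, PPV, NPV,
BAC = (SE+SP)/2, and rank-statistic AUC (ties count ½). The posterior of
BAC takes SE ~ Beta(TP+a, FN+b) and SP ~ Beta(TN+a, FP+b) independently
with a flat Beta(1,1) prior by default (Jeffreys available); the posterior
of their average is computed by numerical convolution on a 4001-point grid
(default) or Monte Carlo. Intervals are central (equal-tailed) 95%.
Significance: P(BAC > 0.5) ≥ 0.95. Monte-Carlo calibration (200 null
confusion matrices at n=50 per class) shows the criterion fires in ≈ 5–9%
of replicates.

## CVR importance

Each retained member's weight vector is normalized to unit Euclidean norm
("normalized weight vector" is read as unit L2; switchable off), pooled
across all outer folds (per-fold pooling available); per feature,
CVR = mean/SE with SE = sd/√K (sample SD, divisor K−1). This makes CVR
exactly the one-sample t statistic of the normalized weights against zero —
the oracle the tests use. Zero-SE features get a NaN sentinel and are
excluded from ranking rather than reported as infinite.

## Sequential risk stratification

Posttest probabilities chain by Bayes' rule through each test's SE/SP;
branch masses follow the law of total probability (leaves sum to 1 and
their probability-weighted posterior equals the pretest to 1e−12, asserted).
Risk bands: high > 80%, medium 40–64%, low < 20%; the uncovered gaps map to
an explicit *indeterminate* category rather than silently extending bins.
NNT = 1/(p·(1−RR)), reported as the exact value plus nearest-integer
rounding; RR is a required parameter with no default (an RR of 0.15
reproduces the canonical 1 / 2–3 / 6 NNT ladder of the two-test worked
example). In the canonical reproduction (pretest 0.40, tests 0.47/0.89 and
0.61/0.64) the (+,−) branch computes to 63.4%; reported values of 64% for
this branch are consistent with less-rounded inputs, so tests hold it to
±1 point while the other three leaves (83/40/19) are exact after integer
rounding.

## Validation experiments and problem sizes

* **Worked-example reproduction** — pure arithmetic, instant.
* **Null calibration** — 200 independent null cohorts (7 sites, ~300
  subjects) through the full LSO pipeline on the clinical view with a
  desk-scale configuration (C grid {0.01, 0.1, 1, 10}, inner k=5, r=2):
  mean out-of-site BAC 0.499, significance rate 8.5% at seed 0.
* **Signal recovery** — 10 seeds of 7×100 cohorts with 8 planted ROIs at
  |d| = 0.8 and clinical effect 0.6: gyrification BAC ≥ 0.65 with posterior
  significance, ≥ 6/8 planted ROIs in the top-10 |CVR|, planted
  reduced-in-bad-outcome ROIs receive negative CVR, and stacking stays
  within 0.02 of the better base model.

The desk-scale inner settings (r=2, 4-point grid) are the package's chosen
simulation sizes for repeated-run studies; single full-size runs use the
k=5, r=10 defaults.

## Numerical choices and edge cases

* Prevalence threshold solved to 1e−10 by Brent's method on an 80-node
  Gauss–Hermite quadrature of the item-exceedance integral.
* Grid-convolution posterior uses FFT convolution of discretized Beta
  masses; grid and 10⁶-draw Monte Carlo agree within 5e−3 on means and
  interval endpoints.
* Hyperparameter ties resolve to the first (smallest) grid value.
* Degenerate pretest probabilities (0 or 1) are returned unchanged with a
  warning rather than raising, since downstream mass computations remain
  valid.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / scikit-learn `random_state`; identical
  configuration and seed give byte-identical artifacts.

## Known limitations

Synthetic cohorts are far friendlier than real multi-site clinical data
(no scanner-by-covariance site effects, no informative missingness, no
label noise); reported recovery rates are upper bounds on real-data
behaviour. The pipeline offers no site harmonization beyond what LSO-CV
tests, no non-linear models, and no threshold tuning. Reproduction of the
original study's real-data accuracies is out of scope because the cohort is
unavailable; only the arithmetic quantities derivable from printed operating
points are reproduced exactly.
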