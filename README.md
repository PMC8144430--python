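# negprog

Prognostic modelling of **negative-symptom outcomes** in individuals at
clinical high risk (CHR) for psychosis.

Negative symptoms (social anhedonia, avolition, blunted emotional
expression, poor occupational functioning) are common in CHR cohorts and
strongly predict later functional impairment, yet prognostic models for
them are scarce. `negprog` implements, as a reusable and fully tested
Python library, the analysis pipeline of a multi-site prognostic study of
9-month negative-symptom outcomes:

* **Outcome labelling** — a subject has a *moderate/severe* outcome when any
  of the SIPS negative items N1, N2, N3, N4, N6 is rated ≥ 3 at follow-up
  (N5, ideational richness, is excluded); social/role functioning is
  *impaired* when the Global Functioning score is ≤ 7.
* **Leave-site-out nested cross-validation (LSO-CV)** — the outer loop holds
  out each recruitment site once (geographic generalizability); the inner
  loop (stratified 5-fold × 10 repeats) selects the L2 regularization of a
  linear classifier (logistic or hinge loss). All inner models at the
  winning hyperparameter form an ensemble whose mean decision score, at
  threshold 0, classifies the held-out site.
* **Stacking** — a meta-classifier of the same linear family combines the
  out-of-site decision scores of the clinical (SIPS-N) and gyrification
  models under the same nested scheme.
* **Posterior balanced accuracy** — with sensitivity ~ Beta(TP+1, FN+1) and
  specificity ~ Beta(TN+1, FP+1), BAC = (SE+SP)/2; a model beats chance when
  P(BAC > 0.5) ≥ 0.95.
* **CVR feature importance** — CVR = mean(*w*)/SE(*w*) over unit-norm
  fold-wise weight vectors; negative CVR means reduced predictor values are
  associated with increased risk.
* **Sequential Bayesian risk stratification** — chaining tests by
  posttest-probability updating,
  p⁺ = p·SE / (p·SE + (1−p)(1−SP)) and p⁻ = p(1−SE) / (p(1−SE) + (1−p)·SP),
  yields a tree of risk groups (high > 80%, medium 40–64%, low < 20%) with
  number-needed-to-treat NNT = 1 / (p·(1−RR)) for an intervention with risk
  ratio RR.
* **Synthetic multi-site cohorts** — the original cohort is not deposited,
  so a first-class generator emulates its structure (7 sites, ordinal SIPS
  items from a latent severity, 68 Desikan–Killiany gyrification ROIs with
  planted effect sizes and site batch offsets, ICV coupling, GF scores) with
  calibrated outcome prevalence and ground-truth metadata for recovery
  tests.

## Worked example

```bash
python examples/risk_stratification.py
```

builds the two-stage stratification tree from a 40% pretest probability,
a clinical test with SE/SP = 0.47/0.89 and a gyrification test with
SE/SP = 0.61/0.64 (risk ratio 0.15 for the NNT column) and prints:

```
tests ++: posttest  82.8%  (high-risk, 13.8% of subjects, NNT 1)
tests +-: posttest  63.4%  (medium-risk, 11.6% of subjects, NNT 2)
tests -+: posttest  40.2%  (medium-risk, 32.2% of subjects, NNT 3)
tests --: posttest  19.5%  (low-risk, 42.4% of subjects, NNT 6)
```

Two positive tests raise the outcome probability from 40% to 83% (high
risk); two negatives lower it to 19% (low risk). The branch masses sum to
one and their probability-weighted posttest values reproduce the pretest
exactly.

`examples/nested_cv_prognosis.py` runs the full LSO-CV pipeline on a
planted-signal synthetic cohort (7 sites × 100 subjects, 8 signal ROIs at
|d| = 0.8) and prints a performance table like:

```
       model  BAC_pct  AUC_pct  SE_pct  SP_pct  PPV_pct  NPV_pct  significant
      SIPS-N       67       72      63      71       58       75         True
gyrification       87       95      86      88       82       91         True
    combined       88       95      88      89       84       92         True
```

Other examples: `simulate_cohort.py` (generator + metadata),
`posterior_balanced_accuracy.py` (grid vs Monte-Carlo posterior),
`feature_importance.py` (CVR recovery of planted ROIs). A thin CLI mirrors
the library (`negprog simulate|label|train|evaluate|stratify|run-all|experiments`).

## Layout

```
src/negprog/      library (synthetic, outcomes, features, nested_cv,
                  metrics, importance, stratification, io, pipeline,
                  experiments, cli)
examples/         narrative scripts, one per capability
tests/            pytest suite
docs/methods.md   model and design notes
```
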