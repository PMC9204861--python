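# Methods

This note documents the statistical procedures the package implements, the
modelling choices behind its synthetic-cohort generator, and the numerical
conventions that matter when interpreting its output.

## The audit

The package audits whether sepsis identification and mortality-risk
prediction behave uniformly across social-determinant subgroups of an ICU
cohort. A patient record carries five determinants (race, sex, marital
status, insurance type, language), three clinical features (SOFA and SIRS
scores over the first 24 h of the ICU stay, and age), ICD-9 codes, the timing
of suspected infection relative to ICU admission, a cardiothoracic-surgery
service flag, and the in-hospital death indicator. The audit has two arms:

1. **Prevalence disparity.** Each patient is labelled under six sepsis
   criteria — five ICD-9 code-set rules (Explicit, Angus, Martin, CMS, CDC)
   and Sepsis-3 (SOFA ≥ 2 with suspected infection within ±24 h of
   admission). For every determinant category and criterion the proportion
   identified as sepsis is reported with a 95% percentile-bootstrap CI.
2. **Performance disparity.** Sixteen classifier configurations are trained
   to predict in-hospital death from min-max-scaled (SOFA, SIRS, age) on a
   7:3 random split of the Sepsis-3 cohort. Each model's test-set AUC on
   every subgroup is compared with the whole test set (one-tailed permutation
   test) and between subgroup pairs (two-tailed permutation test).

## Cohort selection and releveling

Selection is complete-case: adults (age ≥ 18) with suspected infection within
±24 h of ICU admission, not admitted for cardiothoracic surgery services, and
with no missing required field. Raw determinant strings relevel onto fixed
category sets; unmapped race/language values fall to "Other" and marital
status to "Unknown", while an unmapped sex or insurance value is an error
because those determinants define no catch-all category. ICD-9 codes match as
exact strings after stripping whitespace and the dot ("995.92" ≡ "99592");
no other normalization is attempted.

## Bootstrap confidence intervals

The CI for a subgroup proportion resamples that subgroup's flags with
replacement, preserving subgroup size, and takes the percentile interval of
the resampled proportions (1000 resamples by default). Resampling
within-subgroup (rather than re-drawing the whole cohort) matches the
per-subgroup interpretation of the forest plot; the percentile method is the
simplest consistent choice. Two numerical conventions: `ci_level=0` returns
the resampling median for both endpoints, and the interval is clamped to
bracket the point estimate (with few resamples the raw percentile endpoints
can otherwise land entirely on one side of it). The simulated coverage of the
nominal 95% interval at n=200, p=0.3 is computed by `scripts/acceptance.py`
rather than quoted here.

## The classifier harness

`YoudenThresholdClassifier` is an sklearn-compatible estimator wrapping any
scikit-learn classifier that exposes `decision_function` or `predict_proba`.
Fitting tunes the wrapped estimator by mean 5-fold cross-validated AUC over a
hyperparameter grid (stratified, shuffled, seeded folds; ties resolve to the
first grid point), refits the winner on the full training data, and selects
the decision threshold maximizing Youden's J = sensitivity + specificity − 1
on the training scores. Threshold candidates are the midpoints between
adjacent sorted unique scores plus ∓∞ sentinels; ties in J resolve to the
lowest candidate. Choosing the threshold on training scores keeps the test
set untouched for evaluation; this is a design choice of this package, not a
claim about how any particular study did it.

The sixteen configurations are ridge, perceptron, passive-aggressive (in its
SGD formulation — hinge loss, no penalty, PA-I learning rate), kNN, random
forest, linear SVMs with L1/L2 penalties, SGD classifiers with L1/L2/elastic
-net penalties, multinomial and Bernoulli naive Bayes, logistic regression,
and kernel SVMs (rbf, polynomial, sigmoid). Default grids are small and
documented in `models.py` (four log-spaced regularization strengths; kNN
neighbours {3, 5, 11, 21}; forest {100, 300} trees × depth {∞, 5}); nothing
in the method depends on these being optimal and all are overridable.
Multinomial NB sees inputs clipped at 0 (scaled test rows can dip below the
training minimum); Bernoulli NB binarizes scaled features at 0.5; the kernel
SVMs carry a libsvm iteration cap (10^5) so large-C grid points terminate.
Features are scaled to [0,1] with bounds learned from training data only;
test values outside the bounds pass through unclipped.

AUC is the Mann-Whitney rank statistic (ties count ½). A single-class sample
has no AUC; the package returns NaN as an explicit "undefined" signal, which
the permutation machinery propagates as flagged rows rather than errors.

## Permutation tests

The underlying study design never pins down its permutation scheme, so the
package implements the two minimal exchangeability nulls that preserve group
sizes and documents them as an interpretation:

* **Subgroup vs whole.** Statistic: AUC(subgroup) − AUC(whole test set).
  Null: a uniformly random subset of the test set of the subgroup's size
  replaces the subgroup. One-tailed; the tail may be fixed (`"less"` /
  `"greater"`) or follow the sign of the observed difference (`"auto"`, the
  convention used in disparity tables, with the tested direction recorded
  per cell).
* **Pairwise.** Statistic: AUC(A) − AUC(B). Null: pool both groups'
  (score, label) pairs and re-split at random into the original sizes.
  Two-tailed on |difference|. The pool is put in a canonical order before
  splitting so the null does not depend on argument order.

p-values use the add-one convention (1 + #extreme)/(n_perm + 1), which can
never be 0 and makes the fixed-tail test valid at any level (p = 1 is
attainable). A permutation whose resampled group is single-class is redrawn
and the redraw count is reported — it is informative for very small
subgroups. No multiple-testing correction is applied by default (one decision
per cell at α = 0.05); Benjamini–Hochberg can be layered on by the user.

**On the sign-adaptive tail.** `tail="auto"` reports the smaller of the two
one-tailed p-values. Read at level α, that procedure has size close to 2α
under the null — a property of adaptivity itself, not of the implementation.
The package's validity simulation (`simulate_null_type_i`, and acceptance
target t9) therefore evaluates the one-tailed test with its direction fixed
to "less" (the performance-decrease question), whose size the add-one
construction bounds at α. Users wanting strict size control with `"auto"`
should halve α.

## The synthetic-cohort generator

The generator emulates the reference cohort's printed structure; it does not
emulate raw EHR records. Defaults:

* **Determinant marginals**: the packaged reference summary's category
  fractions (e.g. race White 4201/5783). Determinants are sampled
  independently of one another — only marginals are published, and no claim
  of joint realism is made.
* **Features**: age ~ Normal(65, 16²) truncated to [18, 100]; SOFA ~
  Gamma(shape 1.6, scale 2.5), rounded and clipped to [0, 24]; SIRS ~
  Binomial(4, 0.55). The feature families are generator choices made to give
  realistic score ranges; nothing downstream depends on their exact form.
* **Outcome**: logistic in the features scaled by their natural ranges, with
  default coefficients (intercept −4, SOFA 5, SIRS 1, age 1.5) chosen to
  give overall in-hospital mortality around 0.14 and true-score
  discrimination around AUC 0.75.
* **Mortality targets**: when calibrating to a summary table, additive
  per-category log-odds offsets are solved on the realised cohort by cyclic
  scalar root-finding (8 rounds of Brent's method per category) so every
  subgroup's conditional death probability hits its target. The constraints
  overlap across determinants; residuals after the cyclic passes are far
  below binomial sampling noise at any cohort size used here.
* **Infection timing**: Normal(0, 12 h), so a realistic minority of records
  falls outside the ±24 h selection window; cardiothoracic service flag
  Bernoulli(0.03).
* **ICD-9 carriage**: one Bernoulli per code-set criterion (Explicit 0.10,
  Angus 0.40, Martin 0.28, CMS 0.18, CDC 0.33), independent across criteria;
  a qualifying patient carries that criterion's representative code. This
  gives per-criterion prevalence control without asserting any cross-
  criterion overlap structure.

Subgroup distortions (`SubgroupEffect`) create disparity scenarios:
coefficient multipliers (e.g. −1 flips SOFA's effect in one subgroup), a
log-odds shift, and label noise (probability of replacing the outcome with a
fair coin; 1.0 forces the subgroup's expected AUC to 0.5 for any score). An
empty effect map **and** no per-subgroup mortality targets give the exact
exchangeable null: every determinant label independent of (features,
outcome). Note that calibration targets themselves break exchangeability —
subgroups with different mortality rates are a rate disparity — so the
operating-characteristic simulations use `null_spec`, which drops the
targets and gives one determinant a two-category marginal (default 20/80) to
host the test subgroup.

What the generator does **not** model: dependence between determinants,
time-series physiology, length of stay, coding intensity differences between
hospitals, or real code-list semantics (the shipped Angus/Martin/CMS/CDC
sets are small illustrative placeholders). Passing tests on synthetic
cohorts therefore validate the statistical machinery — calibration,
exchangeability, type-I control, coverage, oracle equivalence — not the
clinical realism of any particular disparity estimate.

## Problem sizes and determinism

The packaged demo runs 2,000 synthetic patients through the full pipeline
(16 models, 200 permutations per cell, 200 bootstrap resamples), completing
in a couple of minutes on one CPU; the type-I simulation uses 500 replicates
of a 2,000-patient cohort with 200 permutations each, and the coverage
simulation 500 subgroups of 200 with 500 resamples. These sizes give
Monte-Carlo error small enough for 3-SE acceptance bands while staying
desk-scale; all of them are parameters, not constants.

Every stage seed derives from one master seed by hashing the stage name (and
cell labels), so any stage can be rerun in isolation and an identical config
reproduces a byte-identical artifact bundle (the manifest records the master
seed, derived seeds, config hash, and per-stage row counts).

## Known limitations

* The illustrative code sets make absolute code-set prevalences meaningless;
  only the machinery around them is validated. Supply published lists via
  the criteria config for substantive use.
* The pairwise test's draw-by-draw swap symmetry holds exactly for
  equal-size groups (canonical pooling); for unequal sizes symmetry holds in
  distribution only.
* Bootstrap CIs for very small subgroups (e.g. a handful of self-pay
  patients) are honest about width but percentile intervals undercover
  slightly at small n; the coverage simulation quantifies this at n=200.
* The generator's independence assumptions understate real-world confounding
  between determinants; an optional per-subgroup feature shift would be the
  natural extension point.
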