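# sepsis-audit

Subgroup fairness audit of sepsis identification criteria and mortality-risk
classifiers for ICU cohorts.

Sepsis has no single gold-standard definition: claims-based ICD-9 rules
(explicit codes, Angus, Martin, CMS, CDC) and the clinical Sepsis-3 rule
(SOFA ≥ 2 with suspected infection near ICU admission) identify visibly
different patient populations. When a mortality-risk model is then trained on
one whole cohort, its performance need not transfer uniformly to
social-determinant subgroups — by race, sex, marital status, insurance type,
or language. This package implements the full audit for both concerns:

* **Prevalence disparity** — per-subgroup, per-criterion sepsis proportions
  `p̂ = (flagged members)/(members)` with 95% percentile-bootstrap confidence
  intervals (1000 within-subgroup resamples), emitted as a plot-ready forest
  table.
* **Performance disparity** — sixteen classifier configurations (ridge,
  perceptron, passive-aggressive, kNN, random forest, linear/kernel SVMs,
  SGD variants, naive Bayes, logistic regression) predict in-hospital death
  from min–max-scaled (SOFA, SIRS, age) on a 7:3 split, tuned by 5-fold
  cross-validated AUC and thresholded at Youden's J = sens + spec − 1.
  Disparities are tested with permutation nulls on the AUC difference
  Δ = AUC(subgroup) − AUC(reference): one-tailed subgroup-vs-whole tests
  (random same-size subsets of the test set) and two-tailed pairwise tests
  (pooled re-splits), with add-one p-values p = (1 + #extreme)/(B + 1).

Real patient-level data of this kind is access-restricted, so the package
ships a seeded synthetic-cohort generator calibrated to the published summary
of a 5,783-patient Sepsis-3 cohort (subgroup marginals and per-subgroup
mortality rates), with switches to create exact-null or disparity-injected
scenarios for validating the statistics. See `docs/methods.md` for the model
details and assumptions.

## Worked example

```python
import sepsis_audit as sa

config = sa.demo_config(n_patients=2000, models=["Logistic regression"],
                        n_perm=200, n_boot=200, seed=0)
bundle = sa.run_pipeline(config)   # or write CSVs with out_dir="bundle/"

print(bundle["metrics"].round(4).to_string(index=False))
```

```
              model  Accuracy    AUC  Precision  Recall  F1_binary  F1_macro  Specificity
Logistic regression    0.5991 0.6569     0.2263  0.5811     0.3258    0.5203       0.6027
```

The test-set AUC of 0.657 says a randomly chosen death outranks a randomly
chosen survivor 65.7% of the time; the remaining columns score the Youden
threshold's confusion matrix. The disparity table then asks whether that AUC
holds up per subgroup:

```python
d = bundle["disparity"]
print(d[(d.determinant == "race") & (d.comparison == "vs_whole")]
      [["category", "observed_diff", "p_value", "direction", "significant"]]
      .round(4).to_string(index=False))
```

```
                 category  observed_diff  p_value direction  significant
                    Asian         0.3073   0.0846   greater        False
Black or African American         0.0159   0.4975   greater        False
       Hispanic or Latino        -0.2710   0.0647      less        False
                    Other        -0.0239   0.4229      less        False
                    White         0.0006   0.5572   greater        False
```

Here the 22-patient Hispanic or Latino test subgroup scores 0.27 below the
whole-set AUC, but with 200 permutations that deficit is not significant at
α = 0.05 on this null cohort — exactly the kind of call the permutation test
exists to make. `bundle["forest"]` holds the prevalence table (for example,
0.821 of Asian patients flagged by Sepsis-3, CI [0.714, 0.911] on this
draw), and `bundle["summary"]` the per-category counts, percentages and
mortality rates with their train/test split.

The same pipeline is scriptable from the shell:

```bash
sepsis-audit run-all --config configs/demo.yaml --out demo_bundle
sepsis-audit simulate --n 5783 --seed 1 --out cohort.csv
sepsis-audit forest --cohort cohort.csv --out forest.csv --plot forest.svg
```

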