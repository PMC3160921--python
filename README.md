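# vametrics

Robust performance metrics for validating verbal-autopsy (VA)
cause-of-death assignment methods.

Verbal autopsy assigns causes of death from caregiver interviews where
medical certification is unavailable.  Validation studies compare a
method's assignments against gold-standard causes — but most commonly
reported metrics (specificity, overall concordance, Cohen's kappa,
absolute/relative CSMF error) depend strongly on the cause composition
of the particular test dataset, so results are not comparable across
studies and an inferior method can appear superior on a single test
set.  `vametrics` implements the composition-robust alternatives and
the resampling protocol around them:

* **Chance-corrected concordance** for cause *j* with *N* causes:
  `CCC_j = (sensitivity_j − 1/N) / (1 − 1/N)` — 0 at the accuracy of
  uniform random assignment, 1 at perfection, negative below chance.
  The overall CCC is the equal-weighted mean across causes.
* **Partial chance-corrected concordance** for ranked predictions:
  `PCCC(k) = (C(k) − k/N) / (1 − k/N)`, where `C(k)` is the fraction of
  deaths whose true cause is in the top *k* ranked causes.
* **CSMF accuracy** for cause-specific mortality fractions:
  `1 − Σ_j |pred_j − true_j| / (2·(1 − min_j true_j))`, scaled 0 (worst
  possible method) to 1 (no error) for any number of causes.
* **Dirichlet resampling**: metrics are evaluated across test sets
  whose compositions are drawn uniformly from the simplex
  (Dirichlet with all concentrations 1), resampling records with
  replacement per cause; the median across draws is the headline
  number, with a 0.5% running-median stabilization rule.
* A **misclassification-matrix simulator** with two built-in
  three-cause hypothetical methods that demonstrates the instability
  of the legacy metrics and the paired win-count comparison between
  methods.

The audience is anyone designing or reviewing VA validation studies,
or benchmarking cause-assignment algorithms against gold-standard
deaths.

## Worked example

Simulate 1000 deaths with equal true cause fractions from the built-in
`method1` misclassification matrix, then score the predictions:

```bash
vametrics simulate --matrix method1 --deaths 1000 --seed 7 --output deaths.csv
vametrics evaluate --input deaths.csv --output report.json
```

The dataset CSV is three columns (`id,true_cause,predicted_cause`);
ranked predictions use `id,true_cause,cause_1,prob_1,cause_2,prob_2,…`.
The report (abridged, values rounded) reads:

```
per_cause A: sensitivity 0.686  specificity 0.943  ccc  0.528
per_cause B: sensitivity 0.602  specificity 0.679  ccc  0.404
per_cause C: sensitivity 0.316  specificity 0.678  ccc -0.027
overall:     kappa 0.300  overall_ccc 0.302  csmf_accuracy 0.872
```

Cause C's sensitivity (0.316) is below the 1/3 chance level for three
causes, so its chance-corrected concordance is negative: the method is
worse than guessing for that cause even though "32% correct" sounds
respectable.  The overall CCC (0.302) is the equal-weighted mean of the
three per-cause values.  CSMF accuracy (0.872) is high despite the poor
individual assignment because false positives and misses largely cancel
at this particular composition — exactly why individual-level and
population-level performance must be reported separately, and why a
single composition is not enough:

```bash
vametrics resample-evaluate --input deaths.csv --outdir out/
# median overall CCC      0.3022
# median CSMF accuracy    0.7511
```

This re-evaluates both headline metrics across 500 Dirichlet-resampled
compositions (written per draw to `out/*_trace.csv`): the overall CCC
barely moves from its single-dataset value, while the median CSMF
accuracy (0.751) is well below the flattering single-composition 0.872
— the robust number to report.

Other subcommands: `vametrics compare` (paired per-cause win counts
between two methods), and `vametrics reproduce` (the full built-in
two-method benchmark: metric summary tables, win counts, and the
per-draw data behind kappa-vs-error and estimated-vs-true-CSMF plots).
Matrices are given as built-in names or CSV files with cause labels in
the first row and column.

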