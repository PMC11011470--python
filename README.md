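# triagecut

Cutoff policies, combined-reading triage metrics and calibrated synthetic
cohorts for evaluating multi-entity diagnostic AI scores on chest
radiographs.

## The problem

Commercial chest-radiograph readers emit, for each study, a probability
score in [0, 1] for each of several abnormality entities (here the seven
clinically central ones: adenopathy, atelectasis, fracture, pleural
effusion, pneumonia, pneumothorax, tumor).  Turning those scores into
clinical calls requires a cutoff per entity, and the choice of cutoff is a
policy decision, not a property of the model:

* **Youden policy** — maximize Youden's *J* = sensitivity + specificity − 1
  over the empirical ROC curve, the balanced operating point (ties broken
  toward the lower cutoff, favoring sensitivity);
* **Minimum-sensitivity policy** — the largest cutoff whose sensitivity
  stays at or above a floor (default 95%), i.e. the maximal-specificity
  point subject to a rule-out safety constraint.

Reading all seven entities at once compounds per-entity errors.  The
package implements the conservative patient-level classification for such
combined readings: a patient is a **false negative** if *any* finding was
missed (a correct call elsewhere never rescues a miss), otherwise a
**false positive** if any false alarm was raised, otherwise a completely
correct positive or completely correct negative.  Only the last group —
patients read as fully normal, correctly — can be removed from a
radiologist's worklist, which is what the workload-reduction estimate
quantifies.

The package also fits a concordance regression: the deviation between
score and gold label (score for gold-negatives, 1 − score for
gold-positives), stacked patient × entity, regressed on sex, age,
multimorbidity and a foreign-material flag with standardized coefficients
— a bias audit of which patients attract discordant scores.

Because the validation study this models published only summary statistics
(prevalences, a finding-multiplicity histogram, score quantiles and
moments by gold status, covariate mixes), a synthetic cohort generator
reproduces exactly those marginals so that the entire pipeline runs, and
is tested, without any patient data.

## Worked example

```python
from triagecut import (
    GeneratorConfig, generate_cohort, TriageThresholdModel,
    combined_confusion, derive_metrics, workload_reduction,
)

cohort = generate_cohort(GeneratorConfig.default(), seed=1)   # 477 patients
model = TriageThresholdModel(policy="youden").fit(
    cohort.score_matrix(), cohort.gold_matrix()
)
print(model.cutoffs_["pleural_effusion"])     # 0.3591
print(model.aucs_["pleural_effusion"].auc)    # 0.952

counts = combined_confusion(cohort, model.cutoffs_)
m = derive_metrics(counts)
w = workload_reduction(counts)
print(counts)                                  # tp=53 tn=72 fp=314 fn=38
print(f"{w.auto_negative_fraction:.1%} removable, "
      f"{w.missed_fraction:.1%} with a missed finding")
# 15.1% removable, 8.0% with a missed finding
```

The fitted cutoffs are per-entity Youden optima; the combined counts show
how sharply a seven-entity simultaneous reading degrades relative to
single-entity screening: only 72 of 477 patients are confidently
removable, and 38 carry at least one missed finding.

The same pipeline is available from the shell:

```sh
triagecut simulate --seed 1 --out cohort.csv
triagecut evaluate --cohort cohort.csv --policy youden --policy sens95 --out reports/
triagecut demo --out demo/        # chains both and prints rendered tables
```

`evaluate` writes one per-entity CSV per policy (cutoff, AUC with DeLong
95% CI, confusion counts, sensitivity, specificity, PPV, NPV, FPR, plus
cross-entity average rows in both the arithmetic and the pooled
convention, labelled), a combined-reading CSV, and a regression CSV.

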