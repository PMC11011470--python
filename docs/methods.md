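# Methods

## Empirical ROC and cutoff policies

All classification uses one global call convention: **score ≥ cutoff ⇒
positive**.  Candidate thresholds are the distinct observed score values
plus two sentinels (0, calling everything positive, and a value one ulp
above the maximum score, calling everything negative).  No interpolation
is performed, so every operating point is a realizable finite-sample
classification and every selection rule is an exact scan of a finite set;
this is also what makes the brute-force enumeration oracles in the test
suite exact rather than approximate.

AUC is the trapezoidal area of the empirical curve traversed with
thresholds descending (so false-positive rate and sensitivity are jointly
non-decreasing, which pairs vertices at tied FPR values correctly).  On
this candidate set it coincides with the two-sample rank statistic — ties
counted half — divided by *n₊ n₋*; the suite asserts that identity on
every random instance.  Confidence intervals use the DeLong structural
placement variance.  The normal-scale interval is replaced by a
logit-scale interval when either class has fewer than 10 members, where
the normal approximation misbehaves near 0 and 1; intervals are clipped to
[0, 1] and always bracket the point estimate.

**Youden policy.**  The cutoff maximizing *J* = sensitivity +
specificity − 1.  Ties are broken toward the *lowest* qualifying
threshold, the sensitivity-favoring choice appropriate to screening,
where a false negative is the costly error.  Mathematically tied *J*
values can differ by an ulp when reached through different count ratios,
so the tie scan treats values within 1e−9 of the maximum as tied.

**Minimum-sensitivity policy.**  The largest threshold with sensitivity ≥
the floor (default 0.95).  Because sensitivity is non-increasing in the
threshold, this is equivalently the maximal-specificity point subject to
the constraint, and it always exists (threshold 0 has sensitivity 1).
With floor 1.0 it returns the minimum positive score.

## Confusion algebra and the two averaging conventions

From TP/TN/FP/FN the five rates are sensitivity, specificity, PPV, NPV
and FPR = 1 − specificity.  Zero-denominator rates are NaN with an
explicit `undefined` flag — they occur at extreme cutoffs and must not
silently read as 0.  Cross-entity averages are computed in both
conventions found in published multi-entity tables: **arithmetic** (mean
of per-entity rates) and **pooled** (rates of summed counts).  The two
agree only for homogeneous entities, and published tables in this area
mix them — per-entity averages that match arithmetic means for predictive
values but pooling for FPR, and vice versa in the constrained-policy
table — so reports always carry both, labelled.  Averaged *counts* are
always arithmetic means.

## Conservative combined reading

For a simultaneous reading of all seven entities, each patient receives
exactly one category by strict precedence: any missed finding ⇒
`FN_missed`; else any false alarm ⇒ `FP_any` (regardless of additional
correct positive calls); else `TP_complete` if the patient has findings;
else `TN_complete`.  This precedence is the only ordering under which the
four categories partition the cohort while a true positive elsewhere
never excuses a miss.  Combined rates are derived from the four category
counts — e.g. sensitivity = TP_complete / (TP_complete + FN_missed).
Note this denominator counts *categories*, not all gold-positive
patients: a patient with both a miss and other correct findings sits in
`FN_missed` only.  Because this definition is non-standard, a companion
breakdown with conventional denominators (all gold-positive / all
gold-negative patients) is always emitted alongside, clearly labelled.

Workload reduction is the `TN_complete` fraction of the whole cohort —
patients a rule-out deployment could remove from the reading worklist —
reported together with the miss fraction (its safety cost) and, for
context, the rule-out fraction among truly normal patients.  For
single-entity screening the per-entity TN fraction plays the same role.

## Concordance regression

The outcome is the absolute score–gold deviation: score for a
gold-negative observation, 1 − score for a gold-positive one.  This
single definition makes coefficient signs interpretable on both subsets
with sex dummy-coded 0 = male, 1 = female.  Observations are stacked
patient × entity (7 per patient) and models are fitted separately for
gold-negative and gold-positive observations by OLS on standardized
variables, so coefficients are standardized betas; overall significance
is the F test.  Blockwise (hierarchical) entry reports cumulative R²
after each covariate block; the default is a single block of all four
covariates (sex, age, multimorbidity = the patient's count of
gold-positive findings including the index entity, foreign material).

Stacking reuses patient covariates seven times and therefore understates
standard errors; a cluster-robust (by patient) covariance option is
provided.  A logistic variant (outcome: call disagrees with gold at given
cutoffs, McFadden pseudo-R²) is available for users who prefer a discrete
concordance notion.  Linear OLS is the primary model because standardized
betas and R² are linear-model quantities.  Constant covariates are
dropped with a note; rank-deficient designs raise an error naming the
collinear covariates.

## Synthetic cohort generator

The generator emulates the validation study's published summary
statistics; its defaults are those study conditions (477 patients, 226
findings in 167 patients).

* **Gold labels** are sampled with *exact* marginals, not in expectation:
  per-patient finding counts are a shuffled multiset of the published
  multiplicity histogram (310/116/44/6/1 patients with 0–4 findings), and
  per-entity column sums equal the published prevalence counts
  (13, 34, 33, 66, 31, 6, 43).  A random token deal is repaired by
  marginal-preserving 2×2 swaps; infeasible margins are rejected by the
  Gale–Ryser condition.  Exactness keeps small-cohort tests non-flaky and
  matches the fact that the study reports exact counts.  For cohort sizes
  other than 477 the histogram and prevalences are scaled proportionally
  with a deterministic rounding repair that keeps them mutually
  consistent.
* **Positive scores** are beta-distributed, fitted to the published
  median/IQR per entity (positive scores are reported as non-normal).  A
  two-parameter beta cannot match three quantiles at once, so the fit
  matches the median *exactly* (for each shape *a* there is a unique
  median-matching *b*) and minimizes squared quartile error over the
  remaining degree of freedom.  The median is prioritized because it is
  the quantity the large-sample calibration checks; residual quartile
  error (up to ≈0.04 for the flattest entity) is exposed via a
  fit-quality accessor.  Quantile triples that are exactly realizable
  (uniform; triples generated from a beta) are recovered exactly.
* **Negative scores** are truncated normals on [0, 1].  The parent mean
  and SD are solved so that the *truncated* distribution has the
  published mean/SD — naively truncating a normal at the target moments
  would inflate realized means by up to +0.04 for entities near the 0
  boundary.
* **Covariates**: sex ~ Bernoulli (59.54% male), foreign material ~
  Bernoulli (40.04%), age ~ normal with SD 16.73 centred at 62.1 years
  for patients without findings and shifted +6.5 years for patients with
  findings (matching the published subgroup means of ≈62.1 and ≈68.6),
  clipped to [18, 91] and rounded to whole years.  Clipping shrinks the
  positive-subgroup mean slightly (≈0.4 years); the published overall
  mean (61.4) is itself inconsistent with the two subgroup means, so the
  subgroup means are taken as the calibration targets.
* **Independence limits.**  Entity co-occurrence beyond the multiplicity
  histogram is random, and scores are independent across entities within
  a patient; the study publishes no co-occurrence or correlation
  structure that could pin these down.  Passing calibration tests
  therefore demonstrates marginal fidelity, not joint-structure fidelity:
  conclusions about the combined reading on real data, where entity
  scores are presumably correlated, are illustrative only.
* **Effect injection** (for regression recovery studies): configured
  covariate effects are the *realized* standardized coefficients of the
  final deviations.  Entity composition alone already induces a baseline
  multimorbidity–deviation association in the stacked negative subset
  (patients with findings lack negative observations for exactly their
  low-scoring entities), so the generator measures the baseline
  coefficient vector within each gold-status subset and injects the
  difference, with the scale resolved by fixed-point iteration on the
  final deviation SD.  Clipping deviations to [0, 1] attenuates only
  extreme perturbations.

Everything is driven by one `numpy` Generator seeded from a single
integer; identical config + seed yields byte-identical cohort CSVs.

## Numerical and I/O conventions

Scores are serialized with 6 decimals, which the cohort equality
comparison respects (5e−7 tolerance); all other columns are integers.
Internal metric values are kept at full precision; the display renderer
rounds percentages to one decimal (sensitivity/specificity) or two
(predictive values, FPR), the conventions of published tables in this
area.  Run logs carry no timestamps so that fixed-seed report bundles are
reproducible byte for byte.

## Problem sizes used in validation

The test suite and acceptance script run the study-sized cohort (477
patients) for label-marginal and pipeline checks, an n = 10,000 cohort
for distribution calibration (tolerances derived from sampling error: 4×
the asymptotic median SE per entity for positive medians, ±0.01 for
negative means and covariate fractions), ~1000 random small instances for
the ROC/threshold enumeration oracles, and 20 replicates of ~3100 stacked
negative observations for regression parameter recovery.

## Known limitations

* The generator's independence assumptions above.
* DeLong intervals assume large-ish classes; the logit fallback for
  classes under 10 is a pragmatic, not exact, small-sample treatment.
* The stacked regression ignores within-patient correlation unless the
  cluster-robust option is used.
* Published AUC confidence intervals of the validation study cannot be
  re-derived (raw data unavailable, CI method unstated), so only the
  package's own CI method is tested.
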