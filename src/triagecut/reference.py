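"""Published summary statistics of the validation study the package models.

The source study evaluated a commercial deep-learning chest-radiograph
reader against a two-radiologist consensus gold standard in 477 inpatients,
across seven abnormality entities.  Its raw per-patient data are not
deposited; what it publishes are cohort summary statistics, per-entity
score-distribution summaries conditional on gold status, and the confusion
counts at two operating-point policies.  Those printed values are collected
here verbatim: they are the calibration targets for the synthetic cohort
generator and the inputs to the metric-algebra reproduction checks.

All counts refer to the final cohort of 477 patients with 226 positive
findings in 167 patients.
"""

from __future__ import annotations

from .cohort import ENTITIES
from .metrics import ConfusionCounts

N_PATIENTS = 477
N_FINDINGS = 226
N_POSITIVE_PATIENTS = 167

#: Gold-standard prevalence count per entity.
PREVALENCE: dict[str, int] = {
    "adenopathy": 13,
    "atelectasis": 34,
    "fracture": 33,
    "pleural_effusion": 66,
    "pneumonia": 31,
    "pneumothorax": 6,
    "tumor": 43,
}

#: Patients by number of gold-positive findings (0..4).
MULTIPLICITY_HISTOGRAM: dict[int, int] = {0: 310, 1: 116, 2: 44, 3: 6, 4: 1}

#: Cohort covariates: male fraction, age distribution (clipped to 18-91),
#: foreign-material fraction, and the subgroup age means.
MALE_FRACTION = 0.5954
AGE_MEAN = 61.4
AGE_SD = 16.73
AGE_RANGE = (18, 91)
FOREIGN_MATERIAL_FRACTION = 0.4004
AGE_MEAN_POSITIVE = 68.6
AGE_MEAN_NEGATIVE = 62.1

#: Positive-case score distributions: (median, Q1, Q3) per entity.
POSITIVE_SCORE_QUANTILES: dict[str, tuple[float, float, float]] = {
    "adenopathy": (0.6537, 0.5584, 0.7211),
    "atelectasis": (0.5065, 0.4280, 0.6619),
    "fracture": (0.5353, 0.2416, 0.8071),
    "pleural_effusion": (0.5639, 0.3798, 0.6938),
    "pneumonia": (0.6953, 0.5705, 0.8207),
    "pneumothorax": (0.6570, 0.5016, 0.8133),
    "tumor": (0.6210, 0.4624, 0.8029),
}

#: Negative-case score distributions: (mean, sd) per entity.  The study
#: reports these as normally distributed; samples are truncated to [0, 1].
NEGATIVE_SCORE_MOMENTS: dict[str, tuple[float, float]] = {
    "adenopathy": (0.4668, 0.1311),
    "atelectasis": (0.2358, 0.1858),
    "fracture": (0.2417, 0.1952),
    "pleural_effusion": (0.1581, 0.1411),
    "pneumonia": (0.3747, 0.2273),
    "pneumothorax": (0.2695, 0.1772),
    "tumor": (0.4230, 0.1720),
}

#: Negative-case medians/quartiles, printed for comparability.
NEGATIVE_SCORE_QUANTILES: dict[str, tuple[float, float, float]] = {
    "adenopathy": (0.4556, 0.3696, 0.5599),
    "atelectasis": (0.1738, 0.1067, 0.2964),
    "fracture": (0.1718, 0.1038, 0.3216),
    "pleural_effusion": (0.1048, 0.0612, 0.1940),
    "pneumonia": (0.3403, 0.1924, 0.5368),
    "pneumothorax": (0.2090, 0.1480, 0.3325),
    "tumor": (0.3826, 0.2945, 0.5318),
}

#: Per-entity cutoffs resolved by the study under each policy.
YOUDEN_CUTOFFS: dict[str, float] = {
    "adenopathy": 0.4891,
    "atelectasis": 0.3375,
    "fracture": 0.3853,
    "pleural_effusion": 0.3083,
    "pneumonia": 0.5215,
    "pneumothorax": 0.4876,
    "tumor": 0.4173,
}
EXPLORATORY_CUTOFFS: dict[str, float] = {
    "adenopathy": 0.4891,
    "atelectasis": 0.1978,
    "fracture": 0.0902,
    "pleural_effusion": 0.1429,
    "pneumonia": 0.2976,
    "pneumothorax": 0.1602,
    "tumor": 0.3412,
}

#: Per-entity confusion counts at the Youden-optimal cutoffs.
YOUDEN_COUNTS: dict[str, ConfusionCounts] = {
    "adenopathy": ConfusionCounts(tp=13, tn=269, fp=195, fn=0),
    "atelectasis": ConfusionCounts(tp=28, tn=357, fp=86, fn=6),
    "fracture": ConfusionCounts(tp=23, tn=364, fp=80, fn=10),
    "pleural_effusion": ConfusionCounts(tp=57, tn=355, fp=56, fn=9),
    "pneumonia": ConfusionCounts(tp=27, tn=328, fp=118, fn=4),
    "pneumothorax": ConfusionCounts(tp=5, tn=415, fp=56, fn=1),
    "tumor": ConfusionCounts(tp=38, tn=248, fp=186, fn=5),
}

#: Per-entity confusion counts at the 95%-sensitivity exploratory cutoffs.
EXPLORATORY_COUNTS: dict[str, ConfusionCounts] = {
    "adenopathy": ConfusionCounts(tp=13, tn=269, fp=195, fn=0),
    "atelectasis": ConfusionCounts(tp=33, tn=245, fp=198, fn=1),
    "fracture": ConfusionCounts(tp=32, tn=89, fp=355, fn=1),
    "pleural_effusion": ConfusionCounts(tp=63, tn=259, fp=152, fn=3),
    "pneumonia": ConfusionCounts(tp=30, tn=197, fp=249, fn=1),
    "pneumothorax": ConfusionCounts(tp=6, tn=142, fp=329, fn=0),
    "tumor": ConfusionCounts(tp=41, tn=176, fp=258, fn=2),
}

#: Patient-level combined-reading category counts
#: (tp=TP_complete, tn=TN_complete, fp=FP_any, fn=FN_missed).
COMBINED_COUNTS: dict[str, ConfusionCounts] = {
    "youden": ConfusionCounts(tp=16, tn=62, fp=364, fn=35),
    "min_sensitivity": ConfusionCounts(tp=3, tn=5, fp=461, fn=8),
}

#: Published concordance-regression results (standardized betas) for the
#: gold-negative subset, used to choose realistic injected effect sizes.
REPORTED_NEGATIVE_BETAS = {"multimorbidity": 0.151, "age": 0.089, "sex": -0.038}
REPORTED_NEGATIVE_R2 = 0.042

assert list(PREVALENCE) == list(ENTITIES)
assert sum(PREVALENCE.values()) == N_FINDINGS
assert sum(MULTIPLICITY_HISTOGRAM.values()) == N_PATIENTS
assert sum(k * v for k, v in MULTIPLICITY_HISTOGRAM.items()) == N_FINDINGS
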