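"""Conservative patient-level classification for simultaneous reading of
all seven entities, and workload-reduction estimation.

A patient's combined reading is reduced to one of four mutually exclusive
categories with a strict precedence:

1. FN_missed   — any gold-positive entity was called negative.  A correct
   positive call elsewhere never rescues a miss.
2. FP_any      — no miss, but at least one gold-negative entity was called
   positive, regardless of additional correct positive calls.
3. TP_complete — at least one gold-positive entity, all seven calls correct.
4. TN_complete — no findings and no calls: the fully normal, fully
   correctly read patient that could be removed from a reading worklist.

Combined sensitivity/specificity are derived from these four category
counts (e.g. sensitivity = TP_complete / (TP_complete + FN_missed)); note
this denominator counts categories, not all gold-positive patients, so it
is NOT the standard patient-level sensitivity.  A companion breakdown with
the standard denominators is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .cohort import ENTITIES, Cohort
from .metrics import ConfusionCounts


class PatientCategory(Enum):
    FN_MISSED = "FN_missed"
    FP_ANY = "FP_any"
    TP_COMPLETE = "TP_complete"
    TN_COMPLETE = "TN_complete"


def classify_patient(gold: dict[str, int], calls: dict[str, int]) -> PatientCategory:
    """Assign the conservative combined-reading category for one patient."""
    missing = [e for e in ENTITIES if e not in gold or e not in calls]
    if missing:
        raise ValueError(f"incomplete maps, missing entities: {', '.join(missing)}")
    g = np.array([gold[e] for e in ENTITIES], dtype=int)
    c = np.array([calls[e] for e in ENTITIES], dtype=int)
    return _categorize(g[None, :], c[None, :])[0]


def _categorize(gold: np.ndarray, calls: np.ndarray) -> list[PatientCategory]:
    """Vectorized category assignment for (n, 7) gold/call matrices."""
    miss = ((gold == 1) & (calls == 0)).any(axis=1)
    false_alarm = ((gold == 0) & (calls == 1)).any(axis=1)
    any_pos = (gold == 1).any(axis=1)
    out = []
    for m, fa, ap in zip(miss, false_alarm, any_pos):
        if m:
            out.append(PatientCategory.FN_MISSED)
        elif fa:
            out.append(PatientCategory.FP_ANY)
        elif ap:
            out.append(PatientCategory.TP_COMPLETE)
        else:
            out.append(PatientCategory.TN_COMPLETE)
    return out


def categorize_cohort(cohort: Cohort, cutoffs: dict[str, float]) -> list[PatientCategory]:
    """Per-patient combined-reading categories at per-entity cutoffs."""
    missing = [e for e in ENTITIES if e not in cutoffs]
    if missing:
        raise ValueError(f"missing cutoffs for: {', '.join(missing)}")
    gold = cohort.gold_matrix()
    scores = cohort.score_matrix()
    cut = np.array([cutoffs[e] for e in ENTITIES], dtype=float)
    calls = (scores >= cut[None, :]).astype(int)
    return _categorize(gold, calls)


def combined_confusion(cohort: Cohort, cutoffs: dict[str, float]) -> ConfusionCounts:
    """Patient-level 2x2 table of the four combined-reading categories."""
    cats = categorize_cohort(cohort, cutoffs)
    return ConfusionCounts(
        tp=sum(c is PatientCategory.TP_COMPLETE for c in cats),
        tn=sum(c is PatientCategory.TN_COMPLETE for c in cats),
        fp=sum(c is PatientCategory.FP_ANY for c in cats),
        fn=sum(c is PatientCategory.FN_MISSED for c in cats),
    )


@dataclass(frozen=True)
class WorkloadEstimate:
    """Fractions of the whole cohort relevant to automated triage.

    ``auto_negative_fraction`` — patients the policy reads as completely
    normal, i.e. removable from the worklist.  ``missed_fraction`` —
    patients with at least one missed finding (the safety cost).
    ``auto_negative_of_negatives`` — the same rule-out count relative to
    the truly normal subgroup rather than the whole cohort.
    """

    auto_negative_fraction: float
    missed_fraction: float
    auto_negative_of_negatives: float | None = None


def workload_reduction(counts: ConfusionCounts) -> WorkloadEstimate:
    """Workload estimate from a combined (patient-level) confusion table."""
    if counts.n == 0:
        raise ValueError("empty table")
    n_neg = counts.n_negative
    return WorkloadEstimate(
        auto_negative_fraction=counts.tn / counts.n,
        missed_fraction=counts.fn / counts.n,
        auto_negative_of_negatives=(counts.tn / n_neg) if n_neg else None,
    )


def single_entity_ruleout(counts: ConfusionCounts) -> WorkloadEstimate:
    """Workload estimate when screening for a single entity.

    Here every true-negative call rules the patient out for that entity, so
    the rule-out fraction is the entity-level TN share of all patients.
    """
    if counts.n == 0:
        raise ValueError("empty table")
    n_neg = counts.n_negative
    return WorkloadEstimate(
        auto_negative_fraction=counts.tn / counts.n,
        missed_fraction=counts.fn / counts.n,
        auto_negative_of_negatives=(counts.tn / n_neg) if n_neg else None,
    )


@dataclass(frozen=True)
class StandardPatientBreakdown:
    """Patient-level rates with conventional denominators.

    sensitivity = fully-correct positive patients / all gold-positive
    patients; specificity = fully-correct negative patients / all
    gold-negative patients.  Reported alongside the category-count rates
    because the two differ whenever FN_missed absorbs patients who also
    had false alarms.
    """

    n_gold_positive: int
    n_gold_negative: int
    sensitivity: float
    specificity: float


def standard_patient_breakdown(cohort: Cohort, cutoffs: dict[str, float]) -> StandardPatientBreakdown:
    cats = categorize_cohort(cohort, cutoffs)
    gold_pos = cohort.multimorbidity() > 0
    n_pos = int(gold_pos.sum())
    n_neg = len(cohort) - n_pos
    tp = sum(c is PatientCategory.TP_COMPLETE for c in cats)
    tn = sum(c is PatientCategory.TN_COMPLETE for c in cats)
    return StandardPatientBreakdown(
        n_gold_positive=n_pos,
        n_gold_negative=n_neg,
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
    )
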