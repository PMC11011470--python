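"""Confusion-count algebra and derived diagnostic metrics.

Five rates are derived from a 2x2 table: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), positive predictive value TP/(TP+FP), negative
predictive value TN/(TN+FN), and false positive rate FP/(FP+TN) = 1 -
specificity.  Ratios with a zero denominator are reported as NaN with an
explicit flag, never silently as 0.

Cross-entity averages come in the two conventions used in practice:
"arithmetic" averages the per-entity rates, "pooled" sums the confusion
counts first and derives the rates from the sums.  Both are kept because
published multi-entity tables mix them, and the two only agree when the
entities are homogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import ENTITIES, Cohort

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "fpr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_positive(self) -> int:
        """Gold-standard positives."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Gold-standard negatives."""
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    """The five derived rates plus each count's fraction of the total.

    Rates whose denominator is zero are NaN and listed in ``undefined``.
    All values are proportions in [0, 1]; rendering to percentages happens
    only in the report layer.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fpr: float
    tp_fraction: float
    tn_fraction: float
    fp_fraction: float
    fn_fraction: float
    undefined: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def confusion_counts(calls, gold) -> ConfusionCounts:
    """Tally the 2x2 table of binary calls against binary gold labels."""
    calls = np.asarray(calls, dtype=int)
    gold = np.asarray(gold, dtype=int)
    if calls.shape != gold.shape:
        raise ValueError("calls and gold must have equal length")
    if not (set(np.unique(calls)) <= {0, 1} and set(np.unique(gold)) <= {0, 1}):
        raise ValueError("calls and gold must be binary 0/1")
    tp = int(np.sum((calls == 1) & (gold == 1)))
    tn = int(np.sum((calls == 0) & (gold == 0)))
    fp = int(np.sum((calls == 1) & (gold == 0)))
    fn = int(np.sum((calls == 0) & (gold == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classify_entity(cohort: Cohort, entity: str, cutoff: float) -> np.ndarray:
    """Binary calls for one entity at a cutoff (score >= cutoff is positive)."""
    if entity not in ENTITIES:
        raise ValueError(f"unknown entity: {entity}")
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    scores = cohort.frame[f"score_{entity}"].to_numpy(float)
    return (scores >= cutoff).astype(int)


def derive_metrics(c: ConfusionCounts) -> MetricSet:
    """Compute the five diagnostic rates and count fractions from a table."""
    if c.n == 0:
        raise ValueError("cannot derive metrics from an empty table")
    undefined: set[str] = set()
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity", undefined),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity", undefined),
        ppv=_ratio(c.tp, c.tp + c.fp, "ppv", undefined),
        npv=_ratio(c.tn, c.tn + c.fn, "npv", undefined),
        fpr=_ratio(c.fp, c.fp + c.tn, "fpr", undefined),
        tp_fraction=c.tp / c.n,
        tn_fraction=c.tn / c.n,
        fp_fraction=c.fp / c.n,
        fn_fraction=c.fn / c.n,
        undefined=frozenset(undefined),
    )


@dataclass(frozen=True)
class CrossEntityAverage:
    """Cross-entity average of metrics and counts.

    ``method`` is "arithmetic" (mean of per-entity rates) or "pooled"
    (rates of element-wise summed counts).  Averaged counts are always
    arithmetic means, whichever rate convention is chosen.
    """

    method: str
    metrics: MetricSet
    mean_tp: float
    mean_tn: float
    mean_fp: float
    mean_fn: float


def average_across_entities(counts: list[ConfusionCounts], method: str) -> CrossEntityAverage:
    """Average per-entity confusion tables under one of the two conventions."""
    if not counts:
        raise ValueError("need at least one confusion table")
    if method not in ("arithmetic", "pooled"):
        raise ValueError("method must be 'arithmetic' or 'pooled'")
    k = len(counts)
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    mean_tp = total.tp / k
    mean_tn = total.tn / k
    mean_fp = total.fp / k
    mean_fn = total.fn / k
    n_mean = total.n / k

    if method == "pooled":
        pooled = derive_metrics(total)
        metrics = MetricSet(
            **pooled.as_dict(),
            tp_fraction=mean_tp / n_mean,
            tn_fraction=mean_tn / n_mean,
            fp_fraction=mean_fp / n_mean,
            fn_fraction=mean_fn / n_mean,
            undefined=pooled.undefined,
        )
    else:
        per = [derive_metrics(c) for c in counts]
        undefined = frozenset().union(*(m.undefined for m in per))
        vals = {
            name: float(np.mean([getattr(m, name) for m in per]))
            for name in METRIC_NAMES
        }
        metrics = MetricSet(
            **vals,
            tp_fraction=mean_tp / n_mean,
            tn_fraction=mean_tn / n_mean,
            fp_fraction=mean_fp / n_mean,
            fn_fraction=mean_fn / n_mean,
            undefined=undefined,
        )
    return CrossEntityAverage(
        method=method,
        metrics=metrics,
        mean_tp=mean_tp,
        mean_tn=mean_tn,
        mean_fp=mean_fp,
        mean_fn=mean_fn,
    )
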