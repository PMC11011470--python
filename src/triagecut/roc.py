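"""Empirical ROC curves, AUC with DeLong confidence intervals, and the two
cutoff-selection policies (Youden-optimal and sensitivity-constrained).

Call convention, used globally throughout the package: a score is called
positive iff score >= cutoff.  Candidate thresholds are the distinct
observed score values plus two sentinels (0, which calls everything
positive, and a value just above the maximum score, which calls everything
negative); no interpolation between operating points is performed, so every
selection below is an exact finite scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateRocError(ValueError):
    """ROC analysis is undefined for single-class inputs."""


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve as ordered operating points.

    Points are sorted by increasing threshold; sensitivity is therefore
    non-increasing and specificity non-decreasing along the list.  The
    degenerate endpoints (sens 1 / spec 0 at threshold 0, sens 0 / spec 1
    just above the maximum score) are always included.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def __len__(self) -> int:
        return len(self.thresholds)

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(),
                        self.sensitivity.tolist(),
                        self.specificity.tolist()))


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must bracket the AUC")


@dataclass(frozen=True)
class ThresholdChoice:
    """A resolved cutoff under a named policy.

    ``youden_j`` always equals ``sensitivity_at_cutoff + specificity_at_cutoff - 1``;
    ``constraint`` carries the sensitivity floor for the constrained policy and
    is None for the Youden policy.
    """

    policy: str  # "youden" | "min_sensitivity"
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    youden_j: float
    constraint: float | None = None


def _check_two_class(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if np.any((scores < 0.0) | (scores > 1.0)):
        raise ValueError("scores must lie in [0, 1]")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DegenerateRocError(
            "ROC requires at least one positive and one negative label"
        )
    return scores, labels


def empirical_roc(scores, labels) -> RocCurve:
    """Build the empirical ROC curve of a score against binary labels.

    One operating point per distinct observed score value, plus the two
    sentinel endpoints.  Positive call means score >= threshold.
    """
    scores, labels = _check_two_class(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos

    distinct = np.unique(scores)
    above_max = np.nextafter(distinct[-1], np.inf)
    cand = np.concatenate(([0.0], distinct, [above_max]))
    cand = np.unique(cand)

    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    # count of scores >= t via searchsorted on sorted arrays
    tp = n_pos - np.searchsorted(pos_scores, cand, side="left")
    tn = np.searchsorted(neg_scores, cand, side="left")
    sens = tp / n_pos
    spec = tn / n_neg
    return RocCurve(thresholds=cand, sensitivity=sens, specificity=spec,
                    n_pos=n_pos, n_neg=n_neg)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve in (1 - specificity, sensitivity).

    Equal to the two-sample rank statistic (ties counted half) divided by
    n_pos * n_neg, because the empirical curve has one vertex per distinct
    score value.
    """
    # traverse thresholds descending: both fpr and tpr are then
    # non-decreasing, which pairs tied-fpr vertices correctly
    x = (1.0 - curve.specificity)[::-1]
    y = curve.sensitivity[::-1]
    return float(np.trapezoid(y, x))


def mann_whitney_auc(scores, labels) -> float:
    """AUC via the rank-sum statistic: P(pos > neg) + 0.5 P(pos = neg)."""
    scores, labels = _check_two_class(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via structural placement components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placements: for each positive, fraction of negatives it beats (ties half)
    v10 = np.empty(m)
    v01 = np.empty(n)
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n
    lt = np.searchsorted(pos_sorted, neg, side="left")
    le = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lt + 0.5 * (le - lt)) / m
    a = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return a, float(var)


def auc_with_ci(scores, labels, level: float = 0.95) -> AucEstimate:
    """AUC point estimate with a DeLong confidence interval.

    The interval is computed on the natural scale; when either class has
    fewer than 10 members the normal approximation is poor near the
    boundaries, so a logit-transformed interval is used instead.
    """
    scores, labels = _check_two_class(scores, labels)
    a, var = _delong_variance(scores, labels)
    se = float(np.sqrt(var))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    small = min(n_pos, n_neg) < 10
    if se == 0.0:
        lo = hi = a
    elif small and 0.0 < a < 1.0:
        logit = np.log(a / (1.0 - a))
        se_logit = se / (a * (1.0 - a))
        lo = 1.0 / (1.0 + np.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + np.exp(-(logit + z * se_logit)))
    else:
        lo = a - z * se
        hi = a + z * se
    lo = float(np.clip(lo, 0.0, min(a, 1.0)))
    hi = float(np.clip(hi, max(a, 0.0), 1.0))
    return AucEstimate(auc=a, ci_low=lo, ci_high=hi, level=level)


def youden_optimal_threshold(curve: RocCurve) -> ThresholdChoice:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward the lowest qualifying threshold, which
    favors sensitivity — the natural choice in a screening setting where
    false negatives carry the greater risk.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    # mathematical ties can differ by an ulp (different count ratios), so
    # the lowest-threshold tie-break uses a tolerance band below the max
    best = int(np.nonzero(j >= j.max() - 1e-9)[0][0])
    return ThresholdChoice(
        policy="youden",
        cutoff=float(curve.thresholds[best]),
        sensitivity_at_cutoff=float(curve.sensitivity[best]),
        specificity_at_cutoff=float(curve.specificity[best]),
        youden_j=float(j[best]),
    )


def sensitivity_constrained_threshold(
    curve: RocCurve, min_sens: float = 0.95
) -> ThresholdChoice:
    """Largest cutoff whose sensitivity is >= ``min_sens``.

    Because sensitivity is non-increasing in the threshold, this is also
    the maximal-specificity operating point subject to the constraint.
    Feasibility is guaranteed: threshold 0 calls everything positive and
    has sensitivity 1.
    """
    if not (0.0 < min_sens <= 1.0):
        raise ValueError("min_sens must be in (0, 1]")
    ok = np.nonzero(curve.sensitivity >= min_sens - 1e-12)[0]
    best = int(ok[-1])  # thresholds ascend; last qualifying = largest cutoff
    sens = float(curve.sensitivity[best])
    spec = float(curve.specificity[best])
    return ThresholdChoice(
        policy="min_sensitivity",
        cutoff=float(curve.thresholds[best]),
        sensitivity_at_cutoff=sens,
        specificity_at_cutoff=spec,
        youden_j=sens + spec - 1.0,
        constraint=min_sens,
    )


def curve_to_table(curve: RocCurve):
    """Export the curve as a (threshold, sensitivity, specificity) DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "specificity": curve.specificity,
        }
    )
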