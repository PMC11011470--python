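"""Scikit-learn-style estimators wrapping the package's functional core.

These give the three model-like pieces of the pipeline a fit/predict
surface that composes with sklearn tooling:

* :class:`ThresholdBinarizer` — learns a single cutoff for one score
  column under a named policy and binarizes with the global
  score >= cutoff convention.
* :class:`TriageThresholdModel` — learns one cutoff per entity column and
  produces the multi-label call matrix; combined-reading categories are
  derived from calls plus gold labels.
* :class:`ConcordanceRegression` — standardized-coefficient regression of
  score-gold deviation on patient covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import roc
from .cohort import ENTITIES
from .regression import fit_concordance_model

POLICIES = ("youden", "min_sensitivity")


def _select(curve: roc.RocCurve, policy: str, min_sensitivity: float) -> roc.ThresholdChoice:
    if policy == "youden":
        return roc.youden_optimal_threshold(curve)
    if policy == "min_sensitivity":
        return roc.sensitivity_constrained_threshold(curve, min_sensitivity)
    raise ValueError(f"policy must be one of {POLICIES}")


class ThresholdBinarizer(BaseEstimator, ClassifierMixin):
    """Binary classifier that learns a score cutoff from labeled data.

    Parameters
    ----------
    policy : {"youden", "min_sensitivity"}
        Cutoff-selection rule: maximize Youden's J (ties broken toward the
        lower cutoff) or take the largest cutoff keeping sensitivity at or
        above ``min_sensitivity``.
    min_sensitivity : float
        Sensitivity floor for the constrained policy; ignored otherwise.
    """

    def __init__(self, policy: str = "youden", min_sensitivity: float = 0.95):
        self.policy = policy
        self.min_sensitivity = min_sensitivity

    @staticmethod
    def _column(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a single score column")
        return x

    def fit(self, X, y):
        scores = self._column(X)
        y = np.asarray(y, dtype=int)
        curve = roc.empirical_roc(scores, y)
        choice = _select(curve, self.policy, self.min_sensitivity)
        self.curve_ = curve
        self.choice_ = choice
        self.cutoff_ = choice.cutoff
        self.sensitivity_ = choice.sensitivity_at_cutoff
        self.specificity_ = choice.specificity_at_cutoff
        self.youden_j_ = choice.youden_j
        self.auc_ = roc.auc_with_ci(scores, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise AttributeError("ThresholdBinarizer is not fitted")
        return (self._column(X) >= self.cutoff_).astype(int)

    def score(self, X, y) -> float:
        """Youden's J of the fitted cutoff on new data (not accuracy)."""
        from .metrics import confusion_counts, derive_metrics

        m = derive_metrics(confusion_counts(self.predict(X), np.asarray(y, int)))
        return m.sensitivity + m.specificity - 1.0


class TriageThresholdModel(BaseEstimator, ClassifierMixin):
    """Multi-label cutoff model over the seven entity score columns.

    ``fit`` expects X of shape (n, 7) — scores in canonical entity order —
    and Y of shape (n, 7) — gold labels.  It resolves one cutoff per
    entity under the chosen policy; ``predict`` returns the (n, 7) binary
    call matrix.
    """

    def __init__(self, policy: str = "youden", min_sensitivity: float = 0.95):
        self.policy = policy
        self.min_sensitivity = min_sensitivity

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=int)
        if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != len(ENTITIES):
            raise ValueError(f"X and Y must both be (n, {len(ENTITIES)})")
        self.choices_ = {}
        self.aucs_ = {}
        for k, e in enumerate(ENTITIES):
            curve = roc.empirical_roc(X[:, k], Y[:, k])
            self.choices_[e] = _select(curve, self.policy, self.min_sensitivity)
            self.aucs_[e] = roc.auc_with_ci(X[:, k], Y[:, k])
        self.cutoffs_ = {e: c.cutoff for e, c in self.choices_.items()}
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoffs_"):
            raise AttributeError("TriageThresholdModel is not fitted")
        X = np.asarray(X, dtype=float)
        cut = np.array([self.cutoffs_[e] for e in ENTITIES])
        return (X >= cut[None, :]).astype(int)


class ConcordanceRegression(BaseEstimator, RegressorMixin):
    """Standardized-beta regression of deviation on patient covariates.

    ``fit`` expects the stacked observation table produced by
    :func:`triagecut.regression.build_deviation_table`.  Fitted attributes
    mirror the functional result: ``beta_``, ``pvalues_``, ``r_squared_``,
    ``model_p_``, ``n_obs_``.
    """

    def __init__(
        self,
        subset: str = "gold_negative",
        blocks: list | None = None,
        model: str = "linear",
        cluster_robust: bool = False,
    ):
        self.subset = subset
        self.blocks = blocks
        self.model = model
        self.cluster_robust = cluster_robust

    def fit(self, observations: pd.DataFrame, y=None):
        result = fit_concordance_model(
            observations,
            subset=self.subset,
            blocks=self.blocks,
            model=self.model,
            cluster_robust=self.cluster_robust,
        )
        self.result_ = result
        self.beta_ = result.standardized_beta
        self.pvalues_ = result.coefficient_p
        self.r_squared_ = result.r_squared
        self.model_p_ = result.model_p
        self.n_obs_ = result.n_observations
        # store standardization constants for predict()
        want = 0 if self.subset == "gold_negative" else 1
        data = observations[observations["gold"] == want]
        self._center_ = {c: float(data[c].mean()) for c in result.standardized_beta}
        self._scale_ = {c: float(data[c].std(ddof=1)) for c in result.standardized_beta}
        self._y_center_ = float(data["deviation"].mean())
        self._y_scale_ = float(data["deviation"].std(ddof=1))
        return self

    def predict(self, observations: pd.DataFrame) -> np.ndarray:
        """Fitted deviations on the original [0, 1] scale."""
        if not hasattr(self, "beta_"):
            raise AttributeError("ConcordanceRegression is not fitted")
        z = np.zeros(len(observations))
        for c, b in self.beta_.items():
            col = observations[c].to_numpy(float)
            z += b * (col - self._center_[c]) / self._scale_[c]
        return self._y_center_ + self._y_scale_ * z
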