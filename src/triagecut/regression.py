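"""Blockwise regression of score-gold deviation on patient covariates.

The outcome is the absolute deviation between AI score and gold label:
for a gold-negative observation it is the score itself (how far from a
clean 0), for a gold-positive observation it is 1 - score (how far from a
confident 1).  Observations are stacked patient x entity (7 per patient)
and the model is fitted separately for the gold-negative and gold-positive
subsets, on standardized variables, so coefficients are standardized betas
comparable across covariates.

Stacking reuses each patient's covariates seven times, which understates
uncertainty; a cluster-robust (by patient) covariance option is provided.
A logistic variant with outcome "call disagrees with gold" at given
cutoffs is available for users who prefer a discrete concordance notion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ENTITIES, Cohort

COVARIATES = ("sex", "age", "multimorbidity", "foreign_material")
SUBSETS = ("gold_negative", "gold_positive")


def build_deviation_table(
    cohort: Cohort, cutoffs: dict[str, float] | None = None
) -> pd.DataFrame:
    """Stack the cohort into one row per patient x entity observation.

    Columns: patient_id, entity, gold, deviation, sex, age, multimorbidity,
    foreign_material.  When ``cutoffs`` is given, binary ``call`` and
    ``disagree`` columns are added for the logistic variant.
    """
    frame = cohort.frame
    n = len(frame)
    gold = cohort.gold_matrix()
    scores = cohort.score_matrix()
    multi = gold.sum(axis=1)

    rows = {
        "patient_id": np.repeat(frame["patient_id"].to_numpy(), len(ENTITIES)),
        "entity": np.tile(np.array(ENTITIES), n),
        "gold": gold.ravel(),
        "deviation": np.where(gold == 1, 1.0 - scores, scores).ravel(),
        "sex": np.repeat(frame["sex"].to_numpy(int), len(ENTITIES)),
        "age": np.repeat(frame["age"].to_numpy(int), len(ENTITIES)),
        "multimorbidity": np.repeat(multi, len(ENTITIES)),
        "foreign_material": np.repeat(
            frame["foreign_material"].to_numpy(int), len(ENTITIES)
        ),
    }
    table = pd.DataFrame(rows)
    if cutoffs is not None:
        cut = np.array([cutoffs[e] for e in ENTITIES], dtype=float)
        calls = (scores >= cut[None, :]).astype(int)
        table["call"] = calls.ravel()
        table["disagree"] = (calls != gold).astype(int).ravel()
    return table


@dataclass(frozen=True)
class RegressionResult:
    subset: str
    model: str  # "linear" | "logistic"
    standardized_beta: dict[str, float]
    coefficient_p: dict[str, float]
    r_squared: float
    model_p: float
    n_observations: int
    dropped: tuple[str, ...] = ()
    block_r_squared: tuple[float, ...] = ()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if not sd > 0:  # constant input: propagate NaN for the caller to handle
        return np.full(len(x), np.nan)
    return (x - x.mean()) / sd


def fit_concordance_model(
    observations: pd.DataFrame,
    subset: str,
    blocks: list[list[str]] | None = None,
    model: str = "linear",
    cluster_robust: bool = False,
) -> RegressionResult:
    """OLS (or logistic) fit of deviation (or disagreement) on covariates.

    ``blocks`` is an ordered partition of the covariates; coefficients are
    reported for the full model and ``block_r_squared`` gives the
    cumulative R^2 after each block (hierarchical entry).  The default is
    a single block containing all four covariates.  Constant covariates
    are dropped with a note rather than producing a singular fit.
    """
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    if model not in ("linear", "logistic"):
        raise ValueError("model must be 'linear' or 'logistic'")
    want_gold = 0 if subset == "gold_negative" else 1
    data = observations[observations["gold"] == want_gold]
    if len(data) < 10:
        raise ValueError(f"subset {subset} has fewer than 10 observations")

    if blocks is None:
        blocks = [list(COVARIATES)]
    ordered = [c for block in blocks for c in block]
    if sorted(set(ordered)) != sorted(ordered):
        raise ValueError("blocks must not repeat covariates")

    kept, dropped = [], []
    for c in ordered:
        if data[c].nunique() > 1:
            kept.append(c)
        else:
            dropped.append(c)
    if not kept:
        raise ValueError("all covariates are constant in this subset")

    if model == "linear":
        y = _zscore(data["deviation"].to_numpy(float))
        if np.isnan(y).any():  # constant outcome: betas 0, R^2 0 by convention
            zeros = {c: 0.0 for c in kept}
            return RegressionResult(
                subset=subset, model=model, standardized_beta=zeros,
                coefficient_p={c: 1.0 for c in kept}, r_squared=0.0,
                model_p=1.0, n_observations=len(data), dropped=tuple(dropped),
                block_r_squared=tuple(0.0 for _ in blocks),
            )
    else:
        if "disagree" not in data.columns:
            raise ValueError(
                "logistic model needs a 'disagree' column; build the "
                "deviation table with cutoffs"
            )
        y = data["disagree"].to_numpy(int)

    Xz = np.column_stack([_zscore(data[c].to_numpy(float)) for c in kept])
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Xz)), Xz]))
    if rank < Xz.shape[1] + 1:
        raise ValueError(f"rank-deficient design among covariates {kept}")

    groups = data["patient_id"] if cluster_robust else None
    fit_kw = (
        {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
        if cluster_robust
        else {}
    )

    block_r2: list[float] = []
    if model == "linear":
        for upto in range(1, len(blocks) + 1):
            cols = [c for b in blocks[:upto] for c in b if c in kept]
            if not cols:
                block_r2.append(0.0)
                continue
            Xb = np.column_stack([_zscore(data[c].to_numpy(float)) for c in cols])
            res_b = sm.OLS(y, sm.add_constant(Xb)).fit()
            block_r2.append(float(res_b.rsquared))
        res = sm.OLS(y, sm.add_constant(Xz)).fit(**fit_kw)
        r2 = float(res.rsquared)
        model_p = float(res.f_pvalue)
    else:
        res = sm.Logit(y, sm.add_constant(Xz)).fit(disp=0, **fit_kw)
        r2 = float(res.prsquared)  # McFadden pseudo-R^2
        model_p = float(res.llr_pvalue)
        for upto in range(1, len(blocks) + 1):
            cols = [c for b in blocks[:upto] for c in b if c in kept]
            Xb = np.column_stack([_zscore(data[c].to_numpy(float)) for c in cols])
            block_r2.append(
                float(sm.Logit(y, sm.add_constant(Xb)).fit(disp=0).prsquared)
            )

    betas = {c: float(res.params[i + 1]) for i, c in enumerate(kept)}
    pvals = {c: float(res.pvalues[i + 1]) for i, c in enumerate(kept)}
    return RegressionResult(
        subset=subset,
        model=model,
        standardized_beta=betas,
        coefficient_p=pvals,
        r_squared=r2,
        model_p=model_p,
        n_observations=len(data),
        dropped=tuple(dropped),
        block_r_squared=tuple(block_r2),
    )
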