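"""Pipeline orchestration and rendering of the three report tables.

The full evaluation of a cohort runs: per-entity ROC -> cutoff under each
policy -> confusion counts -> derived metrics -> cross-entity averages in
both conventions; then the conservative combined reading with workload
estimates; then the concordance regression.  Every table is written as CSV
with full-precision values; a text rendering with the conventional
rounding (one decimal for sensitivity/specificity percentages, two for
predictive values and FPR) is available for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import ENTITIES, Cohort, read_cohort
from .combined import (
    combined_confusion,
    standard_patient_breakdown,
    workload_reduction,
)
from .estimators import POLICIES, TriageThresholdModel
from .metrics import (
    ConfusionCounts,
    average_across_entities,
    confusion_counts,
    derive_metrics,
)
from .regression import SUBSETS, build_deviation_table, fit_concordance_model
from .simulate import GeneratorConfig, generate_cohort

TABLE_COLUMNS = [
    "cutoff", "auc", "ci_low", "ci_high", "sensitivity", "specificity",
    "tp", "tn", "fp", "fn", "ppv", "npv", "fpr",
]


@dataclass
class PipelineConfig:
    """Configuration for one evaluation run."""

    cohort_path: str | None = None
    generator: GeneratorConfig | None = None
    policies: tuple[str, ...] = ("youden", "min_sensitivity")
    min_sensitivity: float = 0.95
    averaging: tuple[str, ...] = ("arithmetic", "pooled")
    out_dir: str = "reports"
    seed: int = 0

    def validate(self) -> None:
        if not self.policies:
            raise ValueError("at least one policy is required")
        for p in self.policies:
            if p not in POLICIES:
                raise ValueError(f"unknown policy: {p}")
        if not (0.0 < self.min_sensitivity <= 1.0):
            raise ValueError("min_sensitivity must be in (0, 1]")
        if self.cohort_path is None and self.generator is None:
            raise ValueError("either a cohort path or a generator config is needed")


@dataclass
class PolicyEvaluation:
    policy: str
    cutoffs: dict[str, float]
    counts: dict[str, ConfusionCounts]
    table: pd.DataFrame


@dataclass
class ReportBundle:
    cohort: Cohort
    per_policy: dict[str, PolicyEvaluation]
    combined: pd.DataFrame
    regression: pd.DataFrame
    log: list[str] = field(default_factory=list)


def evaluate_policy(
    cohort: Cohort,
    policy: str,
    min_sensitivity: float = 0.95,
    averaging: tuple[str, ...] = ("arithmetic", "pooled"),
) -> PolicyEvaluation:
    """Per-entity evaluation of one cutoff policy on a cohort."""
    model = TriageThresholdModel(policy=policy, min_sensitivity=min_sensitivity)
    model.fit(cohort.score_matrix(), cohort.gold_matrix())
    calls = model.predict(cohort.score_matrix())
    gold = cohort.gold_matrix()

    counts = {
        e: confusion_counts(calls[:, k], gold[:, k]) for k, e in enumerate(ENTITIES)
    }
    rows = []
    for k, e in enumerate(ENTITIES):
        m = derive_metrics(counts[e])
        a = model.aucs_[e]
        rows.append({
            "row": e, "cutoff": model.cutoffs_[e],
            "auc": a.auc, "ci_low": a.ci_low, "ci_high": a.ci_high,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "tp": counts[e].tp, "tn": counts[e].tn,
            "fp": counts[e].fp, "fn": counts[e].fn,
            "ppv": m.ppv, "npv": m.npv, "fpr": m.fpr,
        })
    for method in averaging:
        avg = average_across_entities([counts[e] for e in ENTITIES], method)
        m = avg.metrics
        rows.append({
            "row": f"average_{method}", "cutoff": math.nan,
            "auc": math.nan, "ci_low": math.nan, "ci_high": math.nan,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "tp": avg.mean_tp, "tn": avg.mean_tn,
            "fp": avg.mean_fp, "fn": avg.mean_fn,
            "ppv": m.ppv, "npv": m.npv, "fpr": m.fpr,
        })
    table = pd.DataFrame(rows, columns=["row"] + TABLE_COLUMNS)
    return PolicyEvaluation(
        policy=policy, cutoffs=dict(model.cutoffs_), counts=counts, table=table
    )


def combined_report(
    cohort: Cohort, cutoffs_by_policy: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Combined-reading table: one column per policy, metric rows.

    Rows cover the four category counts, the category-count rates, the
    workload fractions, and the clearly-labelled standard-denominator
    patient-level sensitivity/specificity.
    """
    data: dict[str, list[float]] = {}
    for policy, cutoffs in cutoffs_by_policy.items():
        c = combined_confusion(cohort, cutoffs)
        m = derive_metrics(c)
        w = workload_reduction(c)
        std = standard_patient_breakdown(cohort, cutoffs)
        data[policy] = [
            m.sensitivity, m.specificity, c.tp, c.tn, c.fp, c.fn,
            m.ppv, m.npv, m.fpr,
            w.auto_negative_fraction, w.missed_fraction,
            std.sensitivity, std.specificity,
        ]
    index = [
        "sensitivity", "specificity", "tp", "tn", "fp", "fn",
        "ppv", "npv", "fpr",
        "auto_negative_fraction", "missed_fraction",
        "standard_sensitivity", "standard_specificity",
    ]
    out = pd.DataFrame(data, index=index)
    out.index.name = "metric"
    return out


def regression_report(cohort: Cohort) -> pd.DataFrame:
    """Concordance-regression table over both gold-status subsets."""
    table = build_deviation_table(cohort)
    rows = []
    for subset in SUBSETS:
        res = fit_concordance_model(table, subset=subset)
        for cov, beta in res.standardized_beta.items():
            rows.append({
                "subset": subset, "term": cov,
                "value": beta, "p": res.coefficient_p[cov],
            })
        rows.append({"subset": subset, "term": "r_squared",
                     "value": res.r_squared, "p": res.model_p})
        rows.append({"subset": subset, "term": "n_observations",
                     "value": res.n_observations, "p": math.nan})
    return pd.DataFrame(rows, columns=["subset", "term", "value", "p"])


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full evaluation and write all artifacts to the output dir."""
    config.validate()
    log: list[str] = []
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        log.append(f"cohort: {config.cohort_path} ({len(cohort)} patients)")
    else:
        cohort = generate_cohort(config.generator, seed=config.seed)
        log.append(f"cohort: generated, {cohort.provenance} ({len(cohort)} patients)")

    per_policy: dict[str, PolicyEvaluation] = {}
    cutoffs_by_policy: dict[str, dict[str, float]] = {}
    for policy in config.policies:
        ev = evaluate_policy(
            cohort, policy, config.min_sensitivity, config.averaging
        )
        per_policy[policy] = ev
        cutoffs_by_policy[policy] = ev.cutoffs
        for e in ENTITIES:
            log.append(f"cutoff[{policy}][{e}] = {ev.cutoffs[e]:.6f}")

    combined = combined_report(cohort, cutoffs_by_policy)
    regression = regression_report(cohort)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for policy, ev in per_policy.items():
        ev.table.to_csv(out / f"per_entity_{policy}.csv", index=False,
                        float_format="%.10g", lineterminator="\n")
    combined.to_csv(out / "combined_reading.csv", float_format="%.10g",
                    lineterminator="\n")
    regression.to_csv(out / "regression.csv", index=False,
                      float_format="%.10g", lineterminator="\n")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return ReportBundle(
        cohort=cohort, per_policy=per_policy, combined=combined,
        regression=regression, log=log,
    )


# ---------------------------------------------------------------------------
# Display rendering with conventional rounding


def format_percent(value: float, decimals: int) -> str:
    """Render a proportion as a percentage string, dropping a trailing
    all-zero fraction for exact 0 and 100 (the usual table convention)."""
    if math.isnan(value):
        return "n/a"
    pct = value * 100.0
    if pct in (0.0, 100.0):
        return f"{pct:.0f}%"
    return f"{pct:.{decimals}f}%"


def render_entity_table(
    counts: dict[str, ConfusionCounts],
    cutoffs: dict[str, float] | None = None,
    aucs: dict[str, tuple[float, float, float]] | None = None,
    averaging: tuple[str, ...] = ("arithmetic", "pooled"),
) -> pd.DataFrame:
    """Text table mirroring a per-entity results layout.

    Rows: cutoff, AUC (CI), sensitivity, specificity, the four counts with
    their cohort percentages, PPV, NPV, FPR.  One column per entity plus
    one per requested averaging convention (labelled).
    """
    entities = [e for e in ENTITIES if e in counts] or list(counts)
    cols: dict[str, list[str]] = {}
    for e in entities:
        c = counts[e]
        m = derive_metrics(c)
        n = c.n
        col = [
            f"{cutoffs[e]:.4f}" if cutoffs else "",
            f"{aucs[e][0]:.3f} ({aucs[e][1]:.2f}-{aucs[e][2]:.2f})" if aucs else "",
            format_percent(m.sensitivity, 1),
            format_percent(m.specificity, 1),
            f"{c.tp} ({c.tp / n * 100:.2f})",
            f"{c.tn} ({c.tn / n * 100:.2f})",
            f"{c.fp} ({c.fp / n * 100:.2f})",
            f"{c.fn} ({c.fn / n * 100:.2f})",
            format_percent(m.ppv, 2),
            format_percent(m.npv, 2),
            format_percent(m.fpr, 2),
        ]
        cols[e] = col
    for method in averaging:
        avg = average_across_entities([counts[e] for e in entities], method)
        m = avg.metrics
        n_mean = (avg.mean_tp + avg.mean_tn + avg.mean_fp + avg.mean_fn)
        cols[f"average ({method})"] = [
            "", "",
            format_percent(m.sensitivity, 1),
            format_percent(m.specificity, 1),
            f"{avg.mean_tp:.2f} ({avg.mean_tp / n_mean * 100:.2f})",
            f"{avg.mean_tn:.2f} ({avg.mean_tn / n_mean * 100:.2f})",
            f"{avg.mean_fp:.2f} ({avg.mean_fp / n_mean * 100:.2f})",
            f"{avg.mean_fn:.2f} ({avg.mean_fn / n_mean * 100:.2f})",
            format_percent(m.ppv, 2),
            format_percent(m.npv, 2),
            format_percent(m.fpr, 2),
        ]
    index = [
        "cutoff", "auc_ci", "sensitivity", "specificity",
        "tp", "tn", "fp", "fn", "ppv", "npv", "fpr",
    ]
    return pd.DataFrame(cols, index=index)


def render_combined_table(counts_by_policy: dict[str, ConfusionCounts]) -> pd.DataFrame:
    """Text table of the combined reading, one column per policy."""
    cols = {}
    for policy, c in counts_by_policy.items():
        m = derive_metrics(c)
        n = c.n
        cols[policy] = [
            format_percent(m.sensitivity, 2),
            format_percent(m.specificity, 2),
            f"{c.tp} ({c.tp / n * 100:.2f})",
            f"{c.tn} ({c.tn / n * 100:.2f})",
            f"{c.fp} ({c.fp / n * 100:.2f})",
            f"{c.fn} ({c.fn / n * 100:.2f})",
            format_percent(m.ppv, 2),
            format_percent(m.npv, 2),
            format_percent(m.fpr, 2),
        ]
    index = ["sensitivity", "specificity", "tp", "tn", "fp", "fn",
             "ppv", "npv", "fpr"]
    return pd.DataFrame(cols, index=index)


def render_tables(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    """Render every table of a bundle with display rounding."""
    out: dict[str, pd.DataFrame] = {}
    for policy, ev in bundle.per_policy.items():
        aucs = {
            e: (row["auc"], row["ci_low"], row["ci_high"])
            for e, (_, row) in zip(ENTITIES, ev.table.iterrows())
        }
        out[f"per_entity_{policy}"] = render_entity_table(
            ev.counts, cutoffs=ev.cutoffs, aucs=aucs
        )
    counts_by_policy = {
        policy: ConfusionCounts(
            tp=int(bundle.combined.loc["tp", policy]),
            tn=int(bundle.combined.loc["tn", policy]),
            fp=int(bundle.combined.loc["fp", policy]),
            fn=int(bundle.combined.loc["fn", policy]),
        )
        for policy in bundle.per_policy
    }
    out["combined"] = render_combined_table(counts_by_policy)
    out["regression"] = bundle.regression.copy()
    return out
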