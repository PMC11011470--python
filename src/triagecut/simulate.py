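"""Synthetic cohort generator calibrated to the validation study's
published summary statistics.

The generator reproduces, by construction or by calibration:

* exact gold-label marginals — the per-entity prevalence counts and the
  per-patient finding-multiplicity histogram are hit exactly, not in
  expectation (sampling a binary matrix with fixed row and column sums);
* per-entity AI-score distributions conditional on gold status — positives
  from a beta distribution fitted to the published median/IQR (scores are
  reported as non-normal), negatives from a normal distribution with the
  published mean/SD truncated to [0, 1];
* covariate structure — sex, age (older among patients with findings) and
  a foreign-material flag;
* optional injected covariate effects on the score-gold deviation, on the
  standardized-beta scale, for regression parameter-recovery studies.

Entity co-occurrence beyond the multiplicity histogram is random, and
scores are independent across entities within a patient; the study
publishes nothing that would pin either down.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import optimize, stats

from . import reference as ref
from .cohort import ENTITIES, Cohort

COVARIATES = ("sex", "age", "multimorbidity", "foreign_material")


# ---------------------------------------------------------------------------
# Score distributions


def _median_matched_b(a: float, median: float) -> float:
    """The unique b for which Beta(a, b) has the given median."""
    f = lambda logb: stats.beta.ppf(0.5, a, np.exp(logb)) - median
    return float(np.exp(optimize.brentq(f, -12.0, 12.0, xtol=1e-13)))


def fit_beta_from_quantiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Fit beta shape parameters (a, b) to a (median, Q1, Q3) triple.

    A two-parameter beta generally cannot hit three quantiles at once, so
    the fit matches the median exactly (for each candidate a there is a
    unique median-matching b) and minimizes the summed squared quartile
    error over the remaining degree of freedom.  Matching the median
    exactly is what keeps large-sample score medians on their published
    targets; residual quartile error above 1e-3 triggers a fit-quality
    warning from :class:`ScoreDistribution`.
    """
    if not (0.0 < q1 < median < q3 < 1.0):
        raise ValueError("quantiles must satisfy 0 < q1 < median < q3 < 1")

    def quartile_error(loga: float) -> float:
        a = float(np.exp(loga))
        b = _median_matched_b(a, median)
        fit_q1, fit_q3 = stats.beta.ppf([0.25, 0.75], a, b)
        return (fit_q1 - q1) ** 2 + (fit_q3 - q3) ** 2

    sol = optimize.minimize_scalar(
        quartile_error, bounds=(-6.0, 8.0), method="bounded",
        options={"xatol": 1e-12},
    )
    a = float(np.exp(sol.x))
    return a, _median_matched_b(a, median)


@functools.lru_cache(maxsize=64)
def _cached_beta_fit(median: float, q1: float, q3: float) -> tuple[float, float]:
    return fit_beta_from_quantiles(median, q1, q3)


@functools.lru_cache(maxsize=64)
def _truncnorm_parent_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [0, 1]-truncation has the given mean and sd.

    Truncation pulls the realized mean toward the center of the interval,
    so sampling a normal at the target moments and truncating would bias
    the mean by up to ~0.04 for distributions near the boundary; solving
    the inverse problem keeps the sampled moments on target.
    """

    def gap(params: np.ndarray) -> np.ndarray:
        mu, log_s = params
        s = np.exp(log_s)
        lo, hi = (0.0 - mu) / s, (1.0 - mu) / s
        m, v = stats.truncnorm.stats(lo, hi, loc=mu, scale=s, moments="mv")
        return np.array([m - mean, np.sqrt(v) - sd])

    sol = optimize.root(gap, x0=np.array([mean, np.log(sd)]), tol=1e-12)
    if not sol.success or np.max(np.abs(gap(sol.x))) > 1e-8:
        raise ValueError(f"cannot match truncated moments mean={mean}, sd={sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass(frozen=True)
class ScoreDistribution:
    """A per-entity score distribution conditional on gold status.

    kind "beta_from_quantiles": parameters = (median, q1, q3) targets, with
    the fitted shape pair available via :meth:`shape`.  kind
    "truncated_normal": parameters = (mean, sd), truncated to [0, 1].
    """

    kind: str
    parameters: tuple[float, ...]

    @classmethod
    def from_quantiles(cls, median: float, q1: float, q3: float) -> "ScoreDistribution":
        return cls(kind="beta_from_quantiles", parameters=(median, q1, q3))

    @classmethod
    def truncated_normal(cls, mean: float, sd: float) -> "ScoreDistribution":
        return cls(kind="truncated_normal", parameters=(mean, sd))

    def shape(self) -> tuple[float, float]:
        if self.kind != "beta_from_quantiles":
            raise ValueError("shape() applies to beta_from_quantiles only")
        return _cached_beta_fit(*self.parameters)

    def fit_residual(self) -> float:
        """Largest absolute quantile error of the fitted beta (0 if exact)."""
        if self.kind != "beta_from_quantiles":
            return 0.0
        a, b = self.shape()
        q1, med, q3 = self.parameters[1], self.parameters[0], self.parameters[2]
        fitted = stats.beta.ppf([0.25, 0.5, 0.75], a, b)
        return float(np.max(np.abs(fitted - [q1, med, q3])))

    def median_se(self, n: int) -> float:
        """Asymptotic standard error of a size-n sample median.

        1 / (2 f(median) sqrt(n)) with f the density of the fitted
        distribution; used to derive calibration tolerances from
        Monte-Carlo error instead of guessing them.
        """
        if self.kind == "beta_from_quantiles":
            a, b = self.shape()
            med = stats.beta.ppf(0.5, a, b)
            dens = stats.beta.pdf(med, a, b)
        else:
            mu, s = _truncnorm_parent_params(*self.parameters)
            lo, hi = (0.0 - mu) / s, (1.0 - mu) / s
            med = stats.truncnorm.ppf(0.5, lo, hi, loc=mu, scale=s)
            dens = stats.truncnorm.pdf(med, lo, hi, loc=mu, scale=s)
        return float(1.0 / (2.0 * dens * np.sqrt(n)))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "beta_from_quantiles":
            a, b = self.shape()
            return rng.beta(a, b, size=size)
        if self.kind == "truncated_normal":
            mu, s = _truncnorm_parent_params(*self.parameters)
            lo, hi = (0.0 - mu) / s, (1.0 - mu) / s
            u = rng.random(size)
            return stats.truncnorm.ppf(u, lo, hi, loc=mu, scale=s)
        raise ValueError(f"unknown distribution kind: {self.kind}")


# ---------------------------------------------------------------------------
# Generator configuration


def _scale_counts(n: int) -> tuple[dict[int, int], dict[str, int]]:
    """Proportionally scale the default histogram and prevalences to size n,
    repairing rounding so the two stay mutually consistent."""
    f = n / ref.N_PATIENTS
    hist = {k: int(round(f * v)) for k, v in ref.MULTIPLICITY_HISTOGRAM.items() if k > 0}
    hist = {k: v for k, v in hist.items()}
    n_with = sum(hist.values())
    if n_with > n:
        raise ValueError(f"cohort size {n} too small for the multiplicity histogram")
    hist[0] = n - n_with
    total_findings = sum(k * v for k, v in hist.items())

    prev = {e: int(round(f * c)) for e, c in ref.PREVALENCE.items()}
    # repair prevalences to match total findings, nudging largest entities first
    order = sorted(ENTITIES, key=lambda e: -prev[e])
    i = 0
    while sum(prev.values()) != total_findings:
        e = order[i % len(order)]
        step = 1 if sum(prev.values()) < total_findings else -1
        if prev[e] + step >= 0:
            prev[e] += step
        i += 1
    return hist, prev


@dataclass
class GeneratorConfig:
    """Everything the generator needs, defaulting to the study conditions."""

    n: int = ref.N_PATIENTS
    prevalence: dict[str, int] = field(default_factory=lambda: dict(ref.PREVALENCE))
    multiplicity_histogram: dict[int, int] = field(
        default_factory=lambda: dict(ref.MULTIPLICITY_HISTOGRAM)
    )
    positive_scores: dict[str, ScoreDistribution] = field(
        default_factory=lambda: {
            e: ScoreDistribution.from_quantiles(m, q1, q3)
            for e, (m, q1, q3) in ref.POSITIVE_SCORE_QUANTILES.items()
        }
    )
    negative_scores: dict[str, ScoreDistribution] = field(
        default_factory=lambda: {
            e: ScoreDistribution.truncated_normal(m, s)
            for e, (m, s) in ref.NEGATIVE_SCORE_MOMENTS.items()
        }
    )
    male_fraction: float = ref.MALE_FRACTION
    age_mean_negative: float = ref.AGE_MEAN_NEGATIVE
    age_shift_positive: float = ref.AGE_MEAN_POSITIVE - ref.AGE_MEAN_NEGATIVE
    age_sd: float = ref.AGE_SD
    age_range: tuple[int, int] = ref.AGE_RANGE
    foreign_material_fraction: float = ref.FOREIGN_MATERIAL_FRACTION
    #: optional standardized covariate effects injected into the deviation
    effects: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def default(cls, n: int = ref.N_PATIENTS, **overrides) -> "GeneratorConfig":
        """Study-condition defaults, with marginals rescaled when n differs."""
        cfg = cls(**overrides) if "n" in overrides else cls(n=n, **overrides)
        if cfg.n != ref.N_PATIENTS and "prevalence" not in overrides:
            hist, prev = _scale_counts(cfg.n)
            cfg.multiplicity_histogram = hist
            cfg.prevalence = prev
        return cfg

    def validate(self) -> None:
        if sum(self.multiplicity_histogram.values()) != self.n:
            raise ValueError("multiplicity histogram must sum to n")
        findings = sum(k * v for k, v in self.multiplicity_histogram.items())
        if sum(self.prevalence.values()) != findings:
            raise ValueError(
                "prevalence counts must sum to the histogram's total findings"
            )
        unknown = set(self.effects) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown effect covariates: {sorted(unknown)}")

    def digest(self) -> str:
        payload = yaml.safe_dump(config_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def config_to_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["positive_scores"] = {
        e: {"kind": s.kind, "parameters": list(s.parameters)}
        for e, s in cfg.positive_scores.items()
    }
    d["negative_scores"] = {
        e: {"kind": s.kind, "parameters": list(s.parameters)}
        for e, s in cfg.negative_scores.items()
    }
    d["age_range"] = list(cfg.age_range)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in ("positive_scores", "negative_scores"):
        if key in d:
            d[key] = {
                e: ScoreDistribution(kind=s["kind"], parameters=tuple(s["parameters"]))
                for e, s in d[key].items()
            }
    if "multiplicity_histogram" in d:
        d["multiplicity_histogram"] = {int(k): int(v) for k, v in d["multiplicity_histogram"].items()}
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    return GeneratorConfig(**d)


def load_config(path) -> GeneratorConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: GeneratorConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Gold-label assignment with exact marginals


def _gale_ryser_feasible(row_sums: np.ndarray, col_sums: np.ndarray) -> bool:
    """Existence of a 0/1 matrix with the given margins (Gale-Ryser)."""
    if row_sums.sum() != col_sums.sum():
        return False
    cols = np.sort(col_sums)[::-1]
    rows = row_sums
    for k in range(1, len(cols) + 1):
        lhs = cols[:k].sum()
        rhs = np.minimum(rows, k).sum()
        if lhs > rhs:
            return False
    return True


def assign_findings(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample an (n, 7) binary gold matrix with exact marginals.

    Row sums follow the multiplicity histogram (as a shuffled multiset) and
    column sums equal the prevalence counts exactly.  A random token deal
    may give a patient the same entity twice; such collisions are repaired
    by marginal-preserving 2x2 swaps.
    """
    config.validate()
    n = config.n
    col_sums = np.array([config.prevalence[e] for e in ENTITIES])
    row_multiset = np.repeat(
        list(config.multiplicity_histogram.keys()),
        list(config.multiplicity_histogram.values()),
    )
    if row_multiset.max(initial=0) > len(ENTITIES):
        raise ValueError("a patient cannot have more findings than entities")
    if not _gale_ryser_feasible(np.sort(row_multiset)[::-1], col_sums):
        raise ValueError("infeasible marginals: no binary matrix exists")

    rows = rng.permutation(row_multiset)
    tokens = rng.permutation(np.repeat(np.arange(len(ENTITIES)), col_sums))

    mat = np.zeros((n, len(ENTITIES)), dtype=int)
    idx = 0
    for i, k in enumerate(rows):
        for t in tokens[idx:idx + k]:
            mat[i, t] += 1
        idx += k

    holders = np.nonzero(rows > 0)[0]
    for _ in range(100_000):
        dup = np.argwhere(mat > 1)
        if len(dup) == 0:
            break
        i, e = dup[rng.integers(len(dup))]
        swapped = False
        for j in rng.permutation(holders):
            if j == i or mat[j, e] > 0:
                continue
            options = np.nonzero((mat[j] > 0) & (mat[i] == 0))[0]
            if len(options):
                f = options[rng.integers(len(options))]
                mat[i, e] -= 1
                mat[i, f] += 1
                mat[j, f] -= 1
                mat[j, e] += 1
                swapped = True
                break
        if not swapped:  # pragma: no cover - extreme marginals only
            raise RuntimeError("swap repair stalled; marginals too extreme")
    else:  # pragma: no cover
        raise RuntimeError("swap repair did not converge")
    return mat


# ---------------------------------------------------------------------------
# Effect injection


def _inject_effects(
    dev: np.ndarray, X: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Perturb deviations so standardized OLS betas equal ``betas``.

    The configured effects are the *realized* standardized coefficients of
    the perturbed deviations, not increments: entity composition alone
    already correlates covariates with the baseline deviation (patients
    with findings lack negative observations for exactly those entities),
    so the injection first measures the baseline coefficient vector and
    then adds whatever linear predictor moves it onto the targets, with
    the scale solved by fixed-point iteration on the final deviation SD.
    Clipping to [0, 1] afterwards attenuates only extreme perturbations.
    """
    Xz = np.empty_like(X, dtype=float)
    for c in range(X.shape[1]):
        col = X[:, c].astype(float)
        sd = col.std()
        Xz[:, c] = 0.0 if sd == 0 else (col - col.mean()) / sd
    if float((Xz @ betas).var()) >= 1.0:
        raise ValueError("injected effects too large: implied R^2 >= 1")
    design = np.column_stack([np.ones(len(Xz)), Xz])
    c0 = np.linalg.lstsq(design, dev, rcond=None)[0][1:]
    s = float(dev.std())
    for _ in range(20):
        g = s * betas - c0
        perturbed = dev + Xz @ g
        s_new = float(perturbed.std())
        if abs(s_new - s) < 1e-12:
            break
        s = s_new
    return np.clip(dev + Xz @ (s * betas - c0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort; deterministic given config and seed."""
    config.validate()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = config.n

    gold = assign_findings(config, rng)
    multimorbidity = gold.sum(axis=1)

    scores = np.zeros((n, len(ENTITIES)))
    for k, e in enumerate(ENTITIES):
        pos = gold[:, k] == 1
        n_pos = int(pos.sum())
        if n_pos:
            scores[pos, k] = config.positive_scores[e].sample(n_pos, rng)
        n_neg = n - n_pos
        if n_neg:
            scores[~pos, k] = config.negative_scores[e].sample(n_neg, rng)
    scores = np.clip(scores, 0.0, 1.0)

    sex = (rng.random(n) < (1.0 - config.male_fraction)).astype(int)  # 1 = female
    lo, hi = config.age_range
    age = rng.normal(config.age_mean_negative, config.age_sd, size=n)
    age = age + config.age_shift_positive * (multimorbidity > 0)
    age = np.clip(np.rint(age), lo, hi).astype(int)
    foreign = (rng.random(n) < config.foreign_material_fraction).astype(int)

    if config.effects:
        betas = np.array([config.effects.get(c, 0.0) for c in COVARIATES])
        X_pat = np.column_stack([sex, age, multimorbidity, foreign]).astype(float)
        # stacked (patient x entity) deviations, perturbed within gold status
        dev = np.where(gold == 1, 1.0 - scores, scores)
        for status in (0, 1):
            mask = gold.ravel() == status
            if mask.sum() < 2:
                continue
            X_obs = np.repeat(X_pat, len(ENTITIES), axis=0)[mask]
            flat = dev.ravel()
            flat[mask] = _inject_effects(flat[mask], X_obs, betas)
            dev = flat.reshape(dev.shape)
        scores = np.where(gold == 1, 1.0 - dev, dev)

    frame_cols: dict[str, object] = {
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "foreign_material": foreign,
    }
    for k, e in enumerate(ENTITIES):
        frame_cols[f"gold_{e}"] = gold[:, k]
        frame_cols[f"score_{e}"] = scores[:, k]

    import pandas as pd

    frame = pd.DataFrame(frame_cols)
    provenance = f"synthetic seed={seed} config={config.digest()}"
    return Cohort(frame, provenance=provenance)
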