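"""Cohort container, validation and CSV round-trip.

A cohort is a rectangular per-patient table: demographic covariates plus,
for each of the seven evaluated abnormality entities, a binary gold-standard
label and a continuous AI probability score in [0, 1].  The canonical entity
ordering (alphabetical) is fixed here and used by every other module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical entity identifiers, in the fixed (alphabetical) output order.
ENTITIES: tuple[str, ...] = (
    "adenopathy",
    "atelectasis",
    "fracture",
    "pleural_effusion",
    "pneumonia",
    "pneumothorax",
    "tumor",
)

#: Canonical CSV column order.
COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "foreign_material",
) + tuple(
    col for e in ENTITIES for col in (f"gold_{e}", f"score_{e}")
)

# Sex coding follows the source study's dummy coding: 0 = male, 1 = female.
SEX_MALE = 0
SEX_FEMALE = 1
_SEX_SIDECAR = {"M": 0, "F": 1, "m": 0, "f": 1}


class CohortSchemaError(ValueError):
    """Raised when a cohort file or table violates the cohort schema."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: covariates plus per-entity gold labels and AI scores."""

    patient_id: str
    age: int
    sex: int
    foreign_material: int
    gold: dict[str, int]
    score: dict[str, float]

    @property
    def multimorbidity(self) -> int:
        """Number of gold-standard-positive findings (0..7)."""
        return int(sum(self.gold.values()))


@dataclass
class Cohort:
    """Ordered collection of patient records backed by a DataFrame.

    Parameters
    ----------
    frame : pandas.DataFrame
        Table with the canonical columns (see :data:`COLUMNS`).
    provenance : str
        Free text describing origin (file path or generator seed/config).
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise CohortSchemaError(f"missing column(s): {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if len(self) != len(other):
            return False
        a, b = self.frame, other.frame
        if not (a["patient_id"].tolist() == b["patient_id"].tolist()):
            return False
        for col in COLUMNS[1:]:
            if col.startswith("score_"):
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float),
                                   atol=5e-7, rtol=0.0):
                    return False
            elif a[col].tolist() != b[col].tolist():
                return False
        return True

    def records(self) -> list[PatientRecord]:
        """Materialize the cohort as a list of :class:`PatientRecord`."""
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            out.append(
                PatientRecord(
                    patient_id=str(d["patient_id"]),
                    age=int(d["age"]),
                    sex=int(d["sex"]),
                    foreign_material=int(d["foreign_material"]),
                    gold={e: int(d[f"gold_{e}"]) for e in ENTITIES},
                    score={e: float(d[f"score_{e}"]) for e in ENTITIES},
                )
            )
        return out

    def gold_matrix(self) -> np.ndarray:
        """(n, 7) int array of gold labels in canonical entity order."""
        return self.frame[[f"gold_{e}" for e in ENTITIES]].to_numpy(int)

    def score_matrix(self) -> np.ndarray:
        """(n, 7) float array of AI scores in canonical entity order."""
        return self.frame[[f"score_{e}" for e in ENTITIES]].to_numpy(float)

    def multimorbidity(self) -> np.ndarray:
        """Per-patient count of gold-positive findings."""
        return self.gold_matrix().sum(axis=1)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every cohort invariant; return a list of violation messages.

    An empty list means the cohort is valid.  Each entry names the
    offending patient_id and field so callers can report precisely.
    """
    frame = cohort.frame
    violations: list[str] = []
    if len(frame) == 0:
        violations.append("cohort is empty")
        return violations

    ids = frame["patient_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    for pid in dup:
        violations.append(f"duplicate patient_id: {pid}")

    for row in frame.itertuples(index=False):
        d = row._asdict()
        pid = d["patient_id"]
        if not float(d["age"]).is_integer() or int(d["age"]) < 18:
            violations.append(f"patient {pid}: age must be an integer >= 18, got {d['age']}")
        for flag in ("sex", "foreign_material"):
            if d[flag] not in (0, 1):
                violations.append(f"patient {pid}: {flag} must be 0 or 1, got {d[flag]}")
        for e in ENTITIES:
            g = d[f"gold_{e}"]
            s = d[f"score_{e}"]
            if pd.isna(g) or g not in (0, 1):
                violations.append(f"patient {pid}: gold_{e} must be 0 or 1, got {g}")
            if pd.isna(s) or not (0.0 <= float(s) <= 1.0):
                violations.append(f"patient {pid}: score_{e} must be in [0, 1], got {s}")
    return violations


def cohort_from_records(records: list[PatientRecord], provenance: str = "") -> Cohort:
    """Assemble a :class:`Cohort` from patient records."""
    rows = []
    for r in records:
        missing = [e for e in ENTITIES if e not in r.gold or e not in r.score]
        if missing:
            raise CohortSchemaError(
                f"patient {r.patient_id}: missing entity entries: {', '.join(missing)}"
            )
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "foreign_material": r.foreign_material,
        }
        for e in ENTITIES:
            row[f"gold_{e}"] = r.gold[e]
            row[f"score_{e}"] = r.score[e]
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return Cohort(frame, provenance=provenance)


def read_cohort(path) -> Cohort:
    """Read and validate a cohort CSV.

    The header must match the canonical schema.  Sex may be given either as
    the integer dummy coding (0 = male, 1 = female) or as M/F letters, which
    are mapped on read.  Any invariant violation raises
    :class:`CohortSchemaError` naming the offending row and column.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    if frame["sex"].dtype == object:
        frame["sex"] = frame["sex"].map(lambda v: _SEX_SIDECAR.get(str(v), v))
    cohort = Cohort(frame, provenance=str(path))
    if len(cohort) > 0:
        problems = validate_cohort(cohort)
        if problems:
            # Attach row numbers (1-based, excluding header) for the report.
            id_to_row = {str(pid): i + 2 for i, pid in enumerate(frame["patient_id"])}
            located = []
            for p in problems:
                row = next((id_to_row[pid] for pid in id_to_row if f"patient {pid}:" in p), None)
                located.append(f"row {row}: {p}" if row else p)
            raise CohortSchemaError(f"{path}: " + "; ".join(located))
        for col in cohort.frame.columns:
            if col == "age" or col in ("sex", "foreign_material") or col.startswith("gold_"):
                cohort.frame[col] = cohort.frame[col].astype(int)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort CSV in canonical column order.

    Scores are serialized with 6 decimal places so that write/read
    round-trips are stable byte-for-byte.
    """
    frame = cohort.frame.copy()
    for e in ENTITIES:
        frame[f"score_{e}"] = frame[f"score_{e}"].map(lambda v: f"{float(v):.6f}")
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
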