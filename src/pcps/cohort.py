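"""Patient-level cohort data model with validated CSV round-trip.

A cohort is an ordered collection of :class:`PatientRecord` objects, one per
patient, carrying demographics, pre-chemotherapy serum biomarkers, the scored
PG-SGA nutritional assessment and the metastasis outcome label.  Any serum
biomarker may be missing; missing values are encoded as empty CSV cells and
are never imputed.

The outcome label ``metastatic`` is stored explicitly even though it is
derivable from TNM stage (stage 4 patients are the metastatic group), and the
two are cross-checked at validation time: the label is the pivot of every
downstream analysis, so redundancy catches data-entry errors early.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as _dc_fields
from pathlib import Path
from typing import Iterator, Optional, Union

import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "CSV_COLUMNS",
    "BIOMARKER_FIELDS",
]

SEX_VALUES = ("male", "female")
SITE_VALUES = ("GEJ_proximal", "distal")
STAGE_VALUES = (3, 4)
PGSGA_CATEGORIES = ("A", "B", "C")

#: serum / anthropometric biomarkers; any of these may be missing
BIOMARKER_FIELDS = ("bmi", "albumin", "prealbumin", "transferrin", "crp", "tlc")

CSV_COLUMNS = [
    "patient_id", "age", "sex", "anatomic_site", "stage", "metastatic",
    "bmi", "albumin", "prealbumin", "transferrin", "crp", "tlc",
    "pgsga_score", "pgsga_category",
]

MANDATORY_COLUMNS = ("patient_id", "metastatic")

AGE_RANGE = (18.0, 100.0)
BMI_RANGE = (10.0, 60.0)


class CohortValidationError(ValueError):
    """Raised when a record or cohort violates a data-model invariant."""


@dataclass
class PatientRecord:
    """One subject's covariates, biomarkers, PG-SGA and outcome label.

    Units follow the source tables: albumin g/dL, prealbumin mg/dL (as
    printed; see the methods note on the prealbumin unit scale), transferrin
    mg/dL, CRP mg/L, TLC 10^9 cells/L, BMI kg/m^2.
    """

    patient_id: str
    age: float
    sex: str
    anatomic_site: str
    stage: int
    metastatic: bool
    bmi: Optional[float] = None
    albumin: Optional[float] = None
    prealbumin: Optional[float] = None
    transferrin: Optional[float] = None
    crp: Optional[float] = None
    tlc: Optional[float] = None
    pgsga_score: Optional[int] = None
    pgsga_category: Optional[str] = None

    def problems(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not self.patient_id:
            errs.append("patient_id is empty")
        if self.sex not in SEX_VALUES:
            errs.append(f"sex {self.sex!r} not in {SEX_VALUES}")
        if self.anatomic_site not in SITE_VALUES:
            errs.append(f"anatomic_site {self.anatomic_site!r} not in {SITE_VALUES}")
        if self.stage not in STAGE_VALUES:
            errs.append(f"stage {self.stage!r} not in {STAGE_VALUES}")
        if self.metastatic != (self.stage == 4):
            errs.append(
                f"metastatic={self.metastatic} inconsistent with stage={self.stage}"
            )
        if not (AGE_RANGE[0] < self.age < AGE_RANGE[1]):
            errs.append(f"age {self.age} outside {AGE_RANGE}")
        if self.bmi is not None and not (BMI_RANGE[0] < self.bmi < BMI_RANGE[1]):
            errs.append(f"bmi {self.bmi} outside {BMI_RANGE}")
        for name in ("albumin", "prealbumin", "transferrin", "crp", "tlc"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                errs.append(f"{name} {v} is not positive")
        if self.pgsga_score is not None and self.pgsga_score < 0:
            errs.append(f"pgsga_score {self.pgsga_score} is negative")
        if self.pgsga_category is not None and self.pgsga_category not in PGSGA_CATEGORIES:
            errs.append(f"pgsga_category {self.pgsga_category!r} not in {PGSGA_CATEGORIES}")
        return errs


@dataclass
class Cohort:
    """An ordered, validated collection of patients plus provenance metadata."""

    patients: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patients:
            raise CohortValidationError("cohort is empty")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate patient_id values")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def validate(self) -> None:
        """Raise :class:`CohortValidationError` on the first invalid record."""
        for p in self.patients:
            errs = p.problems()
            if errs:
                raise CohortValidationError(
                    f"patient {p.patient_id!r}: " + "; ".join(errs)
                )

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame (columns = :data:`CSV_COLUMNS`), NaN = missing."""
        rows = []
        for p in self.patients:
            row = {}
            for f in _dc_fields(PatientRecord):
                v = getattr(p, f.name)
                row[f.name] = math.nan if v is None else v
            rows.append(row)
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        return df


def _parse_float(cell: str, column: str, row: int) -> Optional[float]:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise CohortValidationError(
            f"row {row}: unparseable numeric value {cell!r} in column {column!r}"
        ) from exc


def _parse_bool(cell: str, column: str, row: int) -> bool:
    low = cell.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise CohortValidationError(f"row {row}: unparseable boolean {cell!r} in {column!r}")


def _record_from_row(row: pd.Series, idx: int) -> PatientRecord:
    def cell(name: str) -> str:
        return str(row.get(name, "")).strip()

    score_cell = cell("pgsga_score")
    if score_cell == "":
        score: Optional[int] = None
    else:
        score_f = _parse_float(score_cell, "pgsga_score", idx)
        if score_f != int(score_f):
            raise CohortValidationError(f"row {idx}: pgsga_score {score_cell!r} is not an integer")
        score = int(score_f)
    age = _parse_float(cell("age"), "age", idx)
    stage_f = _parse_float(cell("stage"), "stage", idx)
    return PatientRecord(
        patient_id=cell("patient_id"),
        age=math.nan if age is None else age,
        sex=cell("sex"),
        anatomic_site=cell("anatomic_site"),
        stage=-1 if stage_f is None else int(stage_f),
        metastatic=_parse_bool(cell("metastatic"), "metastatic", idx),
        bmi=_parse_float(cell("bmi"), "bmi", idx),
        albumin=_parse_float(cell("albumin"), "albumin", idx),
        prealbumin=_parse_float(cell("prealbumin"), "prealbumin", idx),
        transferrin=_parse_float(cell("transferrin"), "transferrin", idx),
        crp=_parse_float(cell("crp"), "crp", idx),
        tlc=_parse_float(cell("tlc"), "tlc", idx),
        pgsga_score=score,
        pgsga_category=cell("pgsga_category") or None,
    )


def read_cohort(path: Union[str, Path], strict: bool = True) -> Cohort:
    """Read and validate a cohort CSV.

    In strict mode any invariant violation raises
    :class:`CohortValidationError`; otherwise offending rows are dropped and
    the drop count recorded in ``provenance["dropped_rows"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing mandatory columns: {missing_cols}")
    patients: list[PatientRecord] = []
    dropped = 0
    for idx, row in df.iterrows():
        try:
            rec = _record_from_row(row, int(idx))
            errs = rec.problems()
            if errs:
                raise CohortValidationError(
                    f"row {idx} (patient {rec.patient_id!r}): " + "; ".join(errs)
                )
        except CohortValidationError:
            if strict:
                raise
            dropped += 1
            continue
        patients.append(rec)
    cohort = Cohort(patients, provenance={"source": str(path)})
    if dropped:
        cohort.provenance["dropped_rows"] = dropped
    return cohort


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV such that :func:`read_cohort` reproduces it.

    Floats are written with ``repr`` (shortest round-tripping form), missing
    values as empty cells, so the round-trip is lossless to full precision.
    """
    cohort.validate()
    lines = [",".join(CSV_COLUMNS)]
    for p in cohort.patients:
        cells = []
        for name in CSV_COLUMNS:
            v = getattr(p, name)
            if v is None:
                cells.append("")
            elif isinstance(v, bool):
                cells.append("true" if v else "false")
            elif isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
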