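"""Cohort data model and CSV ingest/export.

A cohort is an ordered collection of :class:`SubjectRecord`.  Each record
holds one subject's fasting sample (glucose, insulin, optionally HbA1c),
demographics, inflammation markers, diabetes history and disease-severity
scores.  All concentrations are stored internally in mmol/L (glucose),
pmol/L (insulin) and mg/dL (haptoglobin, CRP); unit metadata in the CSV is
resolved at ingest.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from .units import convert_glucose, convert_insulin

logger = logging.getLogger(__name__)

KNOWN_MEDICATIONS = frozenset(
    {"metformin", "sitagliptin", "vildagliptin", "saxagliptin",
     "glimepiride", "empagliflozin", "other"}
)

GROUPS = ("HS", "control")
SEXES = ("female", "male")

# Plausibility bounds applied at ingest; values outside are rejected.
GLUCOSE_BOUNDS_MMOLL = (1.0, 50.0)
INSULIN_BOUNDS_PMOLL = (0.0, 3000.0)
HBA1C_BOUNDS_PCT = (3.0, 20.0)

#: CSV column order of the standard cohort file.
CSV_COLUMNS = [
    "subject_id", "group", "sex", "age", "bmi",
    "glucose", "glucose_unit", "insulin", "insulin_unit", "hba1c",
    "haptoglobin", "crp", "ab_positive", "age_dm_dx", "meds",
    "hurley", "sahs", "exacerbations", "regions", "fistulae",
    "nodules", "abscesses",
]

MANDATORY_COLUMNS = {"group", "glucose", "insulin"}


class ValidationError(ValueError):
    """A record violated a cohort invariant."""


@dataclass(frozen=True)
class FastingSample:
    """One subject's fasting laboratory values, in internal units.

    glucose : mmol/L, must lie in (1, 50)
    insulin : pmol/L, must lie in [0, 3000]
    hba1c   : percent, in [3, 20], or None when not measured
    """

    glucose: float
    insulin: float
    hba1c: float | None = None

    def __post_init__(self) -> None:
        lo, hi = GLUCOSE_BOUNDS_MMOLL
        if not (lo <= self.glucose <= hi):
            raise ValidationError(
                f"glucose {self.glucose} mmol/L outside plausibility bounds [{lo}, {hi}]")
        lo, hi = INSULIN_BOUNDS_PMOLL
        if not (lo <= self.insulin <= hi):
            raise ValidationError(
                f"insulin {self.insulin} pmol/L outside plausibility bounds [{lo}, {hi}]")
        if self.hba1c is not None:
            lo, hi = HBA1C_BOUNDS_PCT
            if not (lo <= self.hba1c <= hi):
                raise ValidationError(
                    f"HbA1c {self.hba1c}% outside plausibility bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class SubjectRecord:
    """Full per-subject row.

    Severity fields (hurley, sahs, lesion counts) may be absent for
    controls.  ``antidiabetic_medications`` is empty unless explicitly
    listed.  Concentrations of haptoglobin and CRP are in mg/dL.
    """

    subject_id: str
    group: str
    sex: str
    age: float
    bmi: float
    sample: FastingSample
    haptoglobin: float | None = None
    crp: float | None = None
    beta_cell_antibody_positive: bool | None = None
    age_at_diabetes_diagnosis: float | None = None
    antidiabetic_medications: frozenset[str] = frozenset()
    hurley: int | None = None
    sahs: int | None = None
    exacerbations: int | None = None
    affected_regions: int | None = None
    fistulae: int | None = None
    nodules: int | None = None
    abscesses: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0 or self.bmi <= 0:
            raise ValidationError("age must be >= 0 and bmi > 0")
        unknown = set(self.antidiabetic_medications) - KNOWN_MEDICATIONS
        if unknown:
            raise ValidationError(f"unknown antidiabetic medications: {sorted(unknown)}")
        if self.hurley is not None and self.hurley not in (1, 2, 3):
            raise ValidationError(f"hurley stage must be 1-3, got {self.hurley}")
        for name in ("sahs", "exacerbations", "affected_regions",
                     "fistulae", "nodules", "abscesses"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")


@dataclass
class Cohort:
    """Ordered collection of subjects with a provenance note.

    ``rejected_rows`` records (row_number, reason) pairs for CSV rows that
    failed validation at ingest.
    """

    subjects: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subset(self, predicate) -> "Cohort":
        """New cohort keeping subjects for which ``predicate(record)`` is true."""
        kept = [s for s in self.subjects if predicate(s)]
        return Cohort(kept, provenance=f"{self.provenance} | subset")

    def complete_cases(self, variables: list[str]) -> "Cohort":
        """Drop subjects missing any of the named attributes.

        Variable names refer to :class:`SubjectRecord` attributes, with
        ``glucose``/``insulin``/``hba1c`` resolving into the fasting sample.
        Mirrors the complete-case exclusion used for each analysis table.
        """
        def has(s: SubjectRecord, name: str) -> bool:
            if name in ("glucose", "insulin", "hba1c"):
                return getattr(s.sample, name) is not None
            return getattr(s, name) is not None

        return self.subset(lambda s: all(has(s, v) for v in variables))

    def to_dataframe(self):
        """Flat pandas DataFrame in internal units (one row per subject)."""
        import pandas as pd

        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "age": s.age,
                "bmi": s.bmi,
                "glucose": s.sample.glucose,
                "insulin": s.sample.insulin,
                "hba1c": s.sample.hba1c,
                "haptoglobin": s.haptoglobin,
                "crp": s.crp,
                "ab_positive": s.beta_cell_antibody_positive,
                "age_dm_dx": s.age_at_diabetes_diagnosis,
                "meds": ";".join(sorted(s.antidiabetic_medications)),
                "hurley": s.hurley,
                "sahs": s.sahs,
                "exacerbations": s.exacerbations,
                "regions": s.affected_regions,
                "fistulae": s.fistulae,
                "nodules": s.nodules,
                "abscesses": s.abscesses,
            })
        return pd.DataFrame(rows)


def _parse_optional_float(text: str | None) -> float | None:
    if text is None or text.strip() == "":
        return None
    return float(text)


def _parse_optional_int(text: str | None) -> int | None:
    v = _parse_optional_float(text)
    return None if v is None else int(round(v))


def _parse_optional_bool(text: str | None) -> bool | None:
    if text is None or text.strip() == "":
        return None
    t = text.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {text!r}")


def record_from_row(row: dict, glucose_unit: str = "mmol_L",
                    insulin_unit: str = "pmol_L",
                    subject_id: str | None = None) -> SubjectRecord:
    """Build a validated SubjectRecord from one CSV row (a dict of strings).

    Per-row ``glucose_unit`` / ``insulin_unit`` columns override the
    file-level defaults.
    """
    g_unit = (row.get("glucose_unit") or glucose_unit).strip()
    i_unit = (row.get("insulin_unit") or insulin_unit).strip()
    glucose = convert_glucose(float(row["glucose"]), g_unit)
    insulin = convert_insulin(float(row["insulin"]), i_unit)
    sample = FastingSample(glucose=glucose, insulin=insulin,
                           hba1c=_parse_optional_float(row.get("hba1c")))
    meds_text = (row.get("meds") or "").strip()
    meds = frozenset(m.strip() for m in meds_text.split(";") if m.strip())
    return SubjectRecord(
        subject_id=str(row.get("subject_id") or subject_id),
        group=row["group"].strip(),
        sex=(row.get("sex") or "").strip(),
        age=float(row.get("age", "nan")),
        bmi=float(row.get("bmi", "nan")),
        sample=sample,
        haptoglobin=_parse_optional_float(row.get("haptoglobin")),
        crp=_parse_optional_float(row.get("crp")),
        beta_cell_antibody_positive=_parse_optional_bool(row.get("ab_positive")),
        age_at_diabetes_diagnosis=_parse_optional_float(row.get("age_dm_dx")),
        antidiabetic_medications=meds,
        hurley=_parse_optional_int(row.get("hurley")),
        sahs=_parse_optional_int(row.get("sahs")),
        exacerbations=_parse_optional_int(row.get("exacerbations")),
        affected_regions=_parse_optional_int(row.get("regions")),
        fistulae=_parse_optional_int(row.get("fistulae")),
        nodules=_parse_optional_int(row.get("nodules")),
        abscesses=_parse_optional_int(row.get("abscesses")),
    )


def read_cohort(path, glucose_unit: str = "mmol_L",
                insulin_unit: str = "pmol_L") -> Cohort:
    """Read and validate a cohort CSV.

    Missing mandatory columns (group, glucose, insulin) raise immediately;
    rows failing per-subject invariants are rejected individually and
    reported with their row number in ``Cohort.rejected_rows`` and the log.
    """
    subjects: list[SubjectRecord] = []
    rejected: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = set(reader.fieldnames or [])
        missing = MANDATORY_COLUMNS - header
        if missing:
            raise ValidationError(f"cohort CSV {path} lacks mandatory columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                subjects.append(record_from_row(
                    row, glucose_unit, insulin_unit, subject_id=f"row{i}"))
            except (ValidationError, ValueError) as exc:
                logger.warning("row %d rejected: %s", i, exc)
                rejected.append((i, str(exc)))
    return Cohort(subjects, provenance=f"file:{path}", rejected_rows=rejected)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to the standard CSV layout, in internal units."""
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return format(v, ".10g")
        return str(v)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in cohort:
            writer.writerow([
                fmt(s.subject_id), fmt(s.group), fmt(s.sex), fmt(s.age), fmt(s.bmi),
                fmt(s.sample.glucose), "mmol_L", fmt(s.sample.insulin), "pmol_L",
                fmt(s.sample.hba1c), fmt(s.haptoglobin), fmt(s.crp),
                fmt(s.beta_cell_antibody_positive), fmt(s.age_at_diabetes_diagnosis),
                ";".join(sorted(s.antidiabetic_medications)),
                fmt(s.hurley), fmt(s.sahs), fmt(s.exacerbations),
                fmt(s.affected_regions), fmt(s.fistulae), fmt(s.nodules),
                fmt(s.abscesses),
            ])


def with_sample(record: SubjectRecord, **changes) -> SubjectRecord:
    """Return a copy of ``record`` with fasting-sample fields replaced."""
    return replace(record, sample=replace(record.sample, **changes))
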