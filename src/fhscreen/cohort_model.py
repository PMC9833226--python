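"""Domain types and delimited-file I/O for the angiography-registry cohort.

The screening tool consumes two tables: a registry of coronary-angiography
patients (one row per patient, demographic / risk-factor / treatment /
genetic facts recorded at the baseline angiography) and a longitudinal
laboratory table (one dated analyte result per row).  This module defines
the validated in-memory records for both, the canonical CSV dialect
(comma-separated, UTF-8, ISO-8601 dates, dot decimals), and the derivation
of composite risk-factor status from raw registry fields.

Units are fixed per analyte: lipids in mmol/l, HbA1c in mmol/mol (IFCC),
TSH in mU/l.  A reader rejects rows carrying any other unit rather than
attempting conversion.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Smoking(str, enum.Enum):
    NON_SMOKER = "non-smoker"
    EX_SMOKER = "ex-smoker"
    CURRENT = "current"
    UNKNOWN = "unknown"


class LldStatus(str, enum.Enum):
    """Lipid-lowering drug status at baseline angiography."""

    IN_USE = "in-use"
    PRESCRIBED_NOT_USED = "prescribed-not-used"
    NONE = "none"


class SecondaryFlag(str, enum.Enum):
    """Chart-reviewed conditions that explain hypercholesterolemia."""

    NEPHROTIC_SYNDROME = "nephrotic_syndrome"
    ESRD = "esrd"
    CHOLESTASIS = "cholestasis"
    OFFENDING_MEDICATION = "offending_medication"


class Analyte(str, enum.Enum):
    TC = "TC"
    LDL = "LDL"
    HDL = "HDL"
    TG = "TG"
    HBA1C = "HbA1c"
    TSH = "TSH"


class LdlMethod(str, enum.Enum):
    FRIEDEWALD = "friedewald"
    DIRECT = "direct"
    NA = "n/a"


class GeneticTestType(str, enum.Enum):
    FOUNDER_PANEL = "founder_panel"
    GENE_PANEL = "gene_panel"


class GeneticResult(str, enum.Enum):
    PATHOGENIC = "pathogenic_variant"
    NEGATIVE = "negative"
    VUS = "vus"


#: canonical unit per analyte; any other unit is a row-level rejection
CANONICAL_UNITS: dict[Analyte, str] = {
    Analyte.TC: "mmol/l",
    Analyte.LDL: "mmol/l",
    Analyte.HDL: "mmol/l",
    Analyte.TG: "mmol/l",
    Analyte.HBA1C: "mmol/mol",
    Analyte.TSH: "mU/l",
}


@dataclass(frozen=True)
class FounderVariant:
    """One catalogued founder mutation (population-enriched pathogenic variant)."""

    name: str
    gene: str
    hgvs: str


class GeneticTestRecord(BaseModel):
    """Outcome of FH genetic testing recorded for a patient.

    ``founder_panel`` is the regional four-variant LDLR founder test;
    ``gene_panel`` is NGS sequencing of LDLR/APOB/PCSK9/LDLRAP1.
    """

    model_config = ConfigDict(frozen=True)

    tested: bool
    test_type: Optional[GeneticTestType] = None
    result: Optional[GeneticResult] = None
    variant_id: Optional[str] = None

    @model_validator(mode="after")
    def _result_requires_test(self) -> "GeneticTestRecord":
        if not self.tested and self.result is not None:
            raise ValueError("genetic result present without a recorded test")
        return self


class PatientRecord(BaseModel):
    """One registry row: the patient's baseline-angiography facts.

    ``family_history_early_cad`` is tri-state: ``None`` means the registry
    did not record it (treated as absent when scoring, but counted so the
    information loss is visible in logs).
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    sex: Sex
    birth_date: dt.date
    cad_date: dt.date
    max_stenosis_pct: float
    family_history_early_cad: Optional[bool] = None
    diabetes_dx: bool = False
    diabetes_treatment: bool = False
    hypertension_dx: bool = False
    antihypertensive_meds: bool = False
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    smoking: Smoking = Smoking.UNKNOWN
    bmi: Optional[float] = None
    lld_status: LldStatus = LldStatus.NONE
    secondary_flags: frozenset[SecondaryFlag] = frozenset()
    genetic_test: Optional[GeneticTestRecord] = None
    xanthoma: bool = False
    arcus_before_45: bool = False
    premature_other_vascular: bool = False
    cascade_referred: bool = False

    @field_validator("max_stenosis_pct")
    @classmethod
    def _stenosis_range(cls, v: float) -> float:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"max_stenosis_pct {v} outside [0, 100]")
        return v

    @model_validator(mode="after")
    def _birth_before_cad(self) -> "PatientRecord":
        if self.birth_date >= self.cad_date:
            raise ValueError("birth_date must precede cad_date")
        return self

    @property
    def age_at_cad(self) -> float:
        """Age in fractional years (days / 365.25) at the baseline angiography."""
        return (self.cad_date - self.birth_date).days / 365.25


class LabMeasurement(BaseModel):
    """One dated analyte result; the unit-checked atom of laboratory history."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    date: dt.date
    analyte: Analyte
    value: float
    unit: str
    ldl_method: LdlMethod = LdlMethod.NA

    @field_validator("value")
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"measurement value {v} is negative")
        return v

    @model_validator(mode="after")
    def _unit_canonical(self) -> "LabMeasurement":
        expected = CANONICAL_UNITS[self.analyte]
        if self.unit != expected:
            raise ValueError(
                f"unit {self.unit!r} invalid for {self.analyte.value}; expected {expected!r}"
            )
        return self


class CohortConfig(BaseModel):
    """Every numeric threshold of the screening rules in one place.

    Defaults reproduce the published procedure: premature CAD below 55 y
    (men) / 60 y (women) with >50% stenosis; a lipid flag at TC >=8 or
    LDL-C >=5 mmol/l anywhere in the pre-CAD laboratory history since
    2000-01-01; secondary-cause cutoffs (HbA1c >70 mmol/mol, TSH >10 mU/l,
    TG >10 mmol/l); risk-factor definitions (BP >140/>90, BMI >25, HbA1c
    >42); post-CAD treatment goal LDL-C <=1.8 mmol/l; Friedewald validity
    limit TG <=4.5 mmol/l with the era switch to direct LDL measurement on
    2017-03-30.
    """

    male_age_cutoff: float = 55.0
    female_age_cutoff: float = 60.0
    tc_threshold: float = 8.0
    ldl_threshold: float = 5.0
    threshold_inclusive: bool = True
    stenosis_cutoff: float = 50.0
    lab_window_start: dt.date = dt.date(2000, 1, 1)
    friedewald_era_end: dt.date = dt.date(2017, 3, 30)
    tg_exclusion: float = 10.0
    tsh_cutoff: float = 10.0
    hba1c_uncontrolled: float = 70.0
    hba1c_diabetes: float = 42.0
    sbp_cutoff: float = 140.0
    dbp_cutoff: float = 90.0
    bmi_obesity: float = 25.0
    ldl_goal: float = 1.8
    friedewald_tg_max: float = 4.5
    # pretreatment LDL correction multiplier; deliberately off by default
    # because scoring uses the highest recorded (possibly on-treatment) LDL
    ldl_pretreatment_multiplier: Optional[float] = None

    @model_validator(mode="after")
    def _sane(self) -> "CohortConfig":
        for name in (
            "male_age_cutoff", "female_age_cutoff", "tc_threshold",
            "ldl_threshold", "stenosis_cutoff", "tg_exclusion", "tsh_cutoff",
            "hba1c_uncontrolled", "hba1c_diabetes", "sbp_cutoff", "dbp_cutoff",
            "bmi_obesity", "ldl_goal", "friedewald_tg_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lab_window_start > self.friedewald_era_end:
            raise ValueError("lab_window_start must not exceed friedewald_era_end")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        """Load a config overlay; absent keys keep their defaults."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**data)


# ---------------------------------------------------------------------------
# CSV dialect

REGISTRY_COLUMNS: tuple[str, ...] = (
    "patient_id", "sex", "birth_date", "cad_date", "max_stenosis_pct",
    "family_history_early_cad", "diabetes_dx", "diabetes_treatment",
    "hypertension_dx", "antihypertensive_meds", "sbp", "dbp", "smoking",
    "bmi", "lld_status", "secondary_flags", "genetic_tested",
    "genetic_test_type", "genetic_result", "variant_id", "xanthoma",
    "arcus_before_45", "premature_other_vascular", "cascade_referred",
)

LABS_COLUMNS: tuple[str, ...] = (
    "patient_id", "date", "analyte", "value", "unit", "ldl_method",
)


@dataclass(frozen=True)
class RowRejection:
    """A rejected input row: which file, which row, and why."""

    source: str  # "registry" | "labs"
    row_number: int  # 1-based data-row index (header excluded)
    reason: str


@dataclass
class ValidationReport:
    """Per-file accounting of accepted vs. rejected rows (conservation holds)."""

    registry_rows: int = 0
    labs_rows: int = 0
    rejections: list[RowRejection] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _fmt_tristate(v: Optional[bool]) -> str:
    return "unknown" if v is None else _fmt_bool(v)


def _fmt_opt(v: Optional[float]) -> str:
    return "" if v is None else format(v, "g")


def _parse_bool(s: str, column: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"{column}: expected true/false, got {s!r}")


def _parse_tristate(s: str) -> Optional[bool]:
    if s in ("unknown", ""):
        return None
    return _parse_bool(s, "family_history_early_cad")


def _parse_opt_float(s: str, column: str) -> Optional[float]:
    if s == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"{column}: not a number: {s!r}") from exc


def _parse_date(s: str, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(s)
    except ValueError as exc:
        raise ValueError(f"{column}: not an ISO-8601 date: {s!r}") from exc


def registry_row(p: PatientRecord) -> dict[str, str]:
    """Serialize one patient to the canonical registry-CSV row."""
    g = p.genetic_test
    return {
        "patient_id": p.patient_id,
        "sex": p.sex.value,
        "birth_date": p.birth_date.isoformat(),
        "cad_date": p.cad_date.isoformat(),
        "max_stenosis_pct": format(p.max_stenosis_pct, "g"),
        "family_history_early_cad": _fmt_tristate(p.family_history_early_cad),
        "diabetes_dx": _fmt_bool(p.diabetes_dx),
        "diabetes_treatment": _fmt_bool(p.diabetes_treatment),
        "hypertension_dx": _fmt_bool(p.hypertension_dx),
        "antihypertensive_meds": _fmt_bool(p.antihypertensive_meds),
        "sbp": _fmt_opt(p.sbp),
        "dbp": _fmt_opt(p.dbp),
        "smoking": p.smoking.value,
        "bmi": _fmt_opt(p.bmi),
        "lld_status": p.lld_status.value,
        "secondary_flags": ";".join(sorted(f.value for f in p.secondary_flags)),
        "genetic_tested": _fmt_bool(g.tested) if g else "false",
        "genetic_test_type": g.test_type.value if g and g.test_type else "",
        "genetic_result": g.result.value if g and g.result else "",
        "variant_id": g.variant_id or "" if g else "",
        "xanthoma": _fmt_bool(p.xanthoma),
        "arcus_before_45": _fmt_bool(p.arcus_before_45),
        "premature_other_vascular": _fmt_bool(p.premature_other_vascular),
        "cascade_referred": _fmt_bool(p.cascade_referred),
    }


def _patient_from_row(row: dict[str, str]) -> PatientRecord:
    tested = _parse_bool(row["genetic_tested"], "genetic_tested")
    genetic: Optional[GeneticTestRecord] = None
    if tested or row["genetic_result"]:
        genetic = GeneticTestRecord(
            tested=tested,
            test_type=GeneticTestType(row["genetic_test_type"]) if row["genetic_test_type"] else None,
            result=GeneticResult(row["genetic_result"]) if row["genetic_result"] else None,
            variant_id=row["variant_id"] or None,
        )
    flags = frozenset(
        SecondaryFlag(tok) for tok in row["secondary_flags"].split(";") if tok
    )
    return PatientRecord(
        patient_id=row["patient_id"],
        sex=Sex(row["sex"]),
        birth_date=_parse_date(row["birth_date"], "birth_date"),
        cad_date=_parse_date(row["cad_date"], "cad_date"),
        max_stenosis_pct=float(row["max_stenosis_pct"]),
        family_history_early_cad=_parse_tristate(row["family_history_early_cad"]),
        diabetes_dx=_parse_bool(row["diabetes_dx"], "diabetes_dx"),
        diabetes_treatment=_parse_bool(row["diabetes_treatment"], "diabetes_treatment"),
        hypertension_dx=_parse_bool(row["hypertension_dx"], "hypertension_dx"),
        antihypertensive_meds=_parse_bool(row["antihypertensive_meds"], "antihypertensive_meds"),
        sbp=_parse_opt_float(row["sbp"], "sbp"),
        dbp=_parse_opt_float(row["dbp"], "dbp"),
        smoking=Smoking(row["smoking"]),
        bmi=_parse_opt_float(row["bmi"], "bmi"),
        lld_status=LldStatus(row["lld_status"]),
        secondary_flags=flags,
        genetic_test=genetic,
        xanthoma=_parse_bool(row["xanthoma"], "xanthoma"),
        arcus_before_45=_parse_bool(row["arcus_before_45"], "arcus_before_45"),
        premature_other_vascular=_parse_bool(row["premature_other_vascular"], "premature_other_vascular"),
        cascade_referred=_parse_bool(row["cascade_referred"], "cascade_referred"),
    )


def lab_row(m: LabMeasurement) -> dict[str, str]:
    return {
        "patient_id": m.patient_id,
        "date": m.date.isoformat(),
        "analyte": m.analyte.value,
        "value": format(m.value, "g"),
        "unit": m.unit,
        "ldl_method": m.ldl_method.value,
    }


def _lab_from_row(row: dict[str, str]) -> LabMeasurement:
    return LabMeasurement(
        patient_id=row["patient_id"],
        date=_parse_date(row["date"], "date"),
        analyte=Analyte(row["analyte"]),
        value=float(row["value"]),
        unit=row["unit"],
        ldl_method=LdlMethod(row["ldl_method"]) if row["ldl_method"] else LdlMethod.NA,
    )


def write_registry(patients: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=REGISTRY_COLUMNS)
        w.writeheader()
        for p in patients:
            w.writerow(registry_row(p))


def write_labs(labs: Iterable[LabMeasurement], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=LABS_COLUMNS)
        w.writeheader()
        for m in labs:
            w.writerow(lab_row(m))


def write_cohort(
    patients: Iterable[PatientRecord],
    labs: Iterable[LabMeasurement],
    registry_path: str | Path,
    labs_path: str | Path,
) -> None:
    write_registry(patients, registry_path)
    write_labs(labs, labs_path)


def _check_columns(found: Sequence[str] | None, required: Sequence[str], path: str | Path) -> None:
    found = found or []
    missing = [c for c in required if c not in found]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_cohort(
    registry_path: str | Path,
    labs_path: str | Path,
    config: CohortConfig | None = None,
) -> tuple[list[PatientRecord], list[LabMeasurement], ValidationReport]:
    """Read and validate both cohort tables.

    Structural problems (a missing required column) are hard errors; bad
    individual rows (unparseable dates or numbers, non-canonical units,
    violated record invariants) are collected per row in the returned
    :class:`ValidationReport` rather than aborting the read, so one garbled
    row cannot silently discard a cohort.
    """
    del config  # thresholds do not affect parsing; kept for interface symmetry
    patients: list[PatientRecord] = []
    labs: list[LabMeasurement] = []
    report = ValidationReport()

    with open(registry_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, REGISTRY_COLUMNS, registry_path)
        for i, row in enumerate(reader, start=1):
            report.registry_rows += 1
            try:
                patients.append(_patient_from_row(row))
            except (ValueError, KeyError) as exc:
                report.rejections.append(RowRejection("registry", i, str(exc)))

    with open(labs_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, LABS_COLUMNS, labs_path)
        for i, row in enumerate(reader, start=1):
            report.labs_rows += 1
            try:
                labs.append(_lab_from_row(row))
            except (ValueError, KeyError) as exc:
                report.rejections.append(RowRejection("labs", i, str(exc)))

    return patients, labs, report


# ---------------------------------------------------------------------------
# Risk-factor derivation


def derive_diabetes(
    patient: PatientRecord,
    labs: Sequence[LabMeasurement],
    config: CohortConfig | None = None,
) -> bool:
    """Diabetes status: prior diagnosis, ongoing treatment, or HbA1c above
    the diagnostic cutoff (default >42 mmol/mol) anywhere in the history."""
    cfg = config or CohortConfig()
    if patient.diabetes_dx or patient.diabetes_treatment:
        return True
    return any(
        m.analyte is Analyte.HBA1C and m.value > cfg.hba1c_diabetes
        for m in labs
        if m.patient_id == patient.patient_id
    )


def derive_hypertension(
    patient: PatientRecord,
    config: CohortConfig | None = None,
) -> bool:
    """Hypertension: BP strictly above 140 systolic or 90 diastolic,
    a recorded diagnosis, or antihypertensive medication."""
    cfg = config or CohortConfig()
    if patient.hypertension_dx or patient.antihypertensive_meds:
        return True
    if patient.sbp is not None and patient.sbp > cfg.sbp_cutoff:
        return True
    if patient.dbp is not None and patient.dbp > cfg.dbp_cutoff:
        return True
    return False


def derive_obesity(patient: PatientRecord, config: CohortConfig | None = None) -> Optional[bool]:
    """Obesity (BMI strictly above the cutoff); None when BMI is missing."""
    cfg = config or CohortConfig()
    if patient.bmi is None:
        return None
    return patient.bmi > cfg.bmi_obesity
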