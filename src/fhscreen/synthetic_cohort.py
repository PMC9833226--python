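"""Synthetic registry and laboratory tables.

Two generators live here:

* :func:`flowchart_fixture` — a fully deterministic cohort (no RNG) built
  so that the screening pipeline reproduces the validation study's flow
  chart exactly: 28,295 angiographies, 2,678 premature-CAD patients, 211
  flagged, 49 excluded for secondary causes, 162 analyzed splitting into
  55 possible / 103 probable / 4 definite FH, with 21 genetically tested
  patients (14 probable/definite, 7 possible), 5 pathogenic founder/panel
  results among the tested probable/definite and 2 cascade referrals.
  Group-level categorical marginals (family history, hypertension,
  diabetes, lipid-lowering treatment, post-CAD goal attainment, smoking,
  sex) match the published baseline table.  Individual lipid values are
  synthetic — only their screening bands are constrained — so continuous
  medians/quartiles are plausible rather than exact.

* :func:`simulate_cohort` — a seeded stochastic cohort with a latent FH
  state per patient, for property testing and threshold evaluation.

Bulk strata that the pipeline only counts (non-premature patients,
premature patients below the lipid thresholds) are emitted as minimal
records without laboratory histories; each still independently fails the
rule it is meant to fail.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort_model import (
    Analyte,
    CANONICAL_UNITS,
    GeneticResult,
    GeneticTestRecord,
    GeneticTestType,
    LabMeasurement,
    LldStatus,
    PatientRecord,
    SecondaryFlag,
    Sex,
    Smoking,
)
from .dlcn_engine import ldl_points
from .screening_pipeline import ScreeningReport

_DAY = dt.timedelta(days=1)


def _birth_for_age(cad_date: dt.date, age_years: float) -> dt.date:
    return cad_date - dt.timedelta(days=int(round(age_years * 365.25)))


def _lab(pid: str, date: dt.date, analyte: Analyte, value: float) -> LabMeasurement:
    return LabMeasurement(
        patient_id=pid, date=date, analyte=analyte, value=round(value, 2),
        unit=CANONICAL_UNITS[analyte],
    )


# ---------------------------------------------------------------------------
# Deterministic flow-chart fixture


def _cad_date(i: int) -> dt.date:
    """Spread angiography dates deterministically over 2007-2017."""
    return dt.date(2007, 1, 10) + dt.timedelta(days=(37 * i) % 3800)


@dataclass
class _GroupSpec:
    """Attribute marginals for one analyzed DLCN group."""

    n_male: int
    n_hypertension: int
    n_diabetes: int
    n_lld_in_use: int
    n_lld_prescribed: int
    n_goal: int
    smoking: tuple[int, int, int]  # non, ex, current


_POSSIBLE_MARGINALS = _GroupSpec(
    n_male=42, n_hypertension=32, n_diabetes=9,
    n_lld_in_use=11, n_lld_prescribed=7, n_goal=12, smoking=(18, 11, 26),
)
_PROBDEF_MARGINALS = _GroupSpec(
    n_male=75, n_hypertension=83, n_diabetes=18,
    n_lld_in_use=29, n_lld_prescribed=12, n_goal=32, smoking=(33, 36, 38),
)

# per-patient scoring plan for the analyzed groups:
# (count, family_history, ldl_band_value, tc_value, expected_total)
_POSSIBLE_PLAN = (
    (2, True, 4.5, 8.0, 4),    # flagged via TC >= 8; DLCN 2 + 1 + 1
    (53, False, 5.4, 7.4, 5),  # DLCN 2 + 3
)
_PROBABLE_PLAN = (
    (90, True, 5.4, 7.4, 6),   # DLCN 2 + 1 + 3
    (7, True, 7.0, 8.8, 8),    # DLCN 2 + 1 + 5
    (6, False, 7.0, 8.8, 7),   # DLCN 2 + 5
)
# definite: 3 via LDL >= 8.5 (2 + 1 + 8 = 11), 1 via founder-panel DNA
# (2 + 1 + 3 + 8 = 14)
_DEFINITE_LDL = 3
_FOUNDER_NAMES = ("FH-Helsinki", "FH-North-Karelia", "FH-Pori", "FH-Turku")

# secondary-cause mix for the 49 excluded patients
_EXCLUSION_PLAN = (
    ("tg", 15), ("hba1c", 10), ("tsh", 8), ("esrd", 8), ("medication", 5),
    ("cholestasis", 3),
)

N_TOTAL = 28295
N_PREMATURE = 2678
N_FLAGGED = 211
N_EXCLUDED = 49


def _analyzed_patient(
    pid: str,
    idx: int,
    spec: _GroupSpec,
    family: bool,
    ldl: float,
    tc: float,
    genetic: Optional[GeneticTestRecord],
    cascade: bool,
    patients: list[PatientRecord],
    labs: list[LabMeasurement],
) -> None:
    male = idx < spec.n_male
    sex = Sex.MALE if male else Sex.FEMALE
    age = (48.0 if male else 54.0) + (idx % 5) - 2  # men 46-50, women 52-56
    cad = _cad_date(idx)
    pre = cad - dt.timedelta(days=365)
    post = cad + dt.timedelta(days=180)
    n_non, n_ex, _ = spec.smoking
    if idx < n_non:
        smoking = Smoking.NON_SMOKER
    elif idx < n_non + n_ex:
        smoking = Smoking.EX_SMOKER
    else:
        smoking = Smoking.CURRENT
    if idx < spec.n_lld_in_use:
        lld = LldStatus.IN_USE
    elif idx < spec.n_lld_in_use + spec.n_lld_prescribed:
        lld = LldStatus.PRESCRIBED_NOT_USED
    else:
        lld = LldStatus.NONE
    patients.append(PatientRecord(
        patient_id=pid,
        sex=sex,
        birth_date=_birth_for_age(cad, age),
        cad_date=cad,
        max_stenosis_pct=80.0,
        family_history_early_cad=family,
        diabetes_dx=idx < spec.n_diabetes,
        hypertension_dx=idx < spec.n_hypertension,
        smoking=smoking,
        bmi=26.0 + 2 * (idx % 5),
        lld_status=lld,
        genetic_test=genetic,
        cascade_referred=cascade,
    ))
    # within-band jitter keeps medians realistic without moving any band
    ldl_val = ldl + 0.06 * ((idx % 5) - 2)
    if ldl_points(ldl_val) != ldl_points(ldl) or (ldl >= 5.0) != (ldl_val >= 5.0):
        ldl_val = ldl
    tc_val = tc + 0.1 * ((idx % 5) - 2)
    if tc >= 8.0:
        tc_val = max(tc_val, tc)  # a TC-driven flag must stay above threshold
    labs.append(_lab(pid, pre, Analyte.LDL, ldl_val))
    labs.append(_lab(pid, pre, Analyte.TC, tc_val))
    labs.append(_lab(pid, post, Analyte.LDL, 1.7 if idx < spec.n_goal else 2.6))


def flowchart_fixture() -> tuple[list[PatientRecord], list[LabMeasurement]]:
    """Deterministic cohort reproducing the study flow chart exactly."""
    patients: list[PatientRecord] = []
    labs: list[LabMeasurement] = []

    # ---- analyzed: possible FH (55) -------------------------------------
    tested_possible = 7
    i = 0
    for count, family, ldl, tc, _total in _POSSIBLE_PLAN:
        for _ in range(count):
            pid = f"FA{i:05d}"
            genetic = None
            # test 7 possible-FH patients (founder panel, negative);
            # skip the 2 TC-flagged patients so bands stay untangled
            if not family and i - 2 < tested_possible:
                genetic = GeneticTestRecord(
                    tested=True, test_type=GeneticTestType.FOUNDER_PANEL,
                    result=GeneticResult.NEGATIVE,
                )
            _analyzed_patient(
                pid, i, _POSSIBLE_MARGINALS, family, ldl, tc, genetic, False,
                patients, labs,
            )
            i += 1

    # ---- analyzed: probable FH (103) ------------------------------------
    i = 0
    for count, family, ldl, tc, _total in _PROBABLE_PLAN:
        for _ in range(count):
            pid = f"FB{i:05d}"
            genetic = None
            if i == 0:
                # follow-up NGS finding: pathogenic on the gene panel, not
                # part of the founder-panel facts the score is built from
                genetic = GeneticTestRecord(
                    tested=True, test_type=GeneticTestType.GENE_PANEL,
                    result=GeneticResult.PATHOGENIC, variant_id="LDLR c.1775G>A",
                )
            elif i in (1, 2):
                genetic = GeneticTestRecord(
                    tested=True, test_type=GeneticTestType.GENE_PANEL,
                    result=GeneticResult.NEGATIVE,
                )
            elif 3 <= i <= 9:
                genetic = GeneticTestRecord(
                    tested=True, test_type=GeneticTestType.FOUNDER_PANEL,
                    result=GeneticResult.NEGATIVE,
                )
            _analyzed_patient(
                pid, i, _PROBDEF_MARGINALS, family, ldl, tc, genetic, False,
                patients, labs,
            )
            i += 1

    # ---- analyzed: definite FH (4) --------------------------------------
    for j in range(_DEFINITE_LDL):
        pid = f"FC{j:05d}"
        genetic = GeneticTestRecord(
            tested=True, test_type=GeneticTestType.FOUNDER_PANEL,
            result=GeneticResult.PATHOGENIC, variant_id=_FOUNDER_NAMES[j],
        )
        _analyzed_patient(
            pid, 103 + j, _PROBDEF_MARGINALS, True, 8.6, 10.5, genetic,
            cascade=(j == 0), patients=patients, labs=labs,
        )
    pid = "FC00003"
    genetic = GeneticTestRecord(
        tested=True, test_type=GeneticTestType.FOUNDER_PANEL,
        result=GeneticResult.PATHOGENIC, variant_id=_FOUNDER_NAMES[3],
    )
    _analyzed_patient(
        pid, 106, _PROBDEF_MARGINALS, True, 5.4, 7.4, genetic, cascade=True,
        patients=patients, labs=labs,
    )

    # ---- flagged but excluded for a secondary cause (49) -----------------
    i = 0
    for kind, count in _EXCLUSION_PLAN:
        for _ in range(count):
            pid = f"FE{i:05d}"
            male = i % 4 != 3  # ~3:1
            cad = _cad_date(i + 7)
            pre = cad - dt.timedelta(days=400)
            flags: frozenset[SecondaryFlag] = frozenset()
            if kind == "esrd":
                flags = frozenset({SecondaryFlag.ESRD})
            elif kind == "medication":
                flags = frozenset({SecondaryFlag.OFFENDING_MEDICATION})
            elif kind == "cholestasis":
                flags = frozenset({SecondaryFlag.CHOLESTASIS})
            patients.append(PatientRecord(
                patient_id=pid,
                sex=Sex.MALE if male else Sex.FEMALE,
                birth_date=_birth_for_age(cad, 48.0 if male else 54.0),
                cad_date=cad,
                max_stenosis_pct=80.0,
                family_history_early_cad=False,
                smoking=Smoking.CURRENT,
                secondary_flags=flags,
            ))
            labs.append(_lab(pid, pre, Analyte.LDL, 5.6))
            if kind == "tg":
                labs.append(_lab(pid, pre, Analyte.TG, 12.0))
            elif kind == "hba1c":
                labs.append(_lab(pid, pre, Analyte.HBA1C, 75.0))
            elif kind == "tsh":
                labs.append(_lab(pid, pre, Analyte.TSH, 12.0))
            i += 1

    # ---- premature CAD, below the lipid thresholds (2467) ----------------
    n_quiet = N_PREMATURE - N_FLAGGED
    for i in range(n_quiet):
        pid = f"FP{i:05d}"
        male = i % 10 < 7
        cad = _cad_date(i)
        patients.append(PatientRecord(
            patient_id=pid,
            sex=Sex.MALE if male else Sex.FEMALE,
            birth_date=_birth_for_age(cad, (47.0 if male else 53.0) + (i % 7)),
            cad_date=cad,
            max_stenosis_pct=75.0,
            family_history_early_cad=(None if i % 7 == 6 else False),
            smoking=Smoking.EX_SMOKER if i % 3 == 0 else Smoking.NON_SMOKER,
        ))
        if i < 10:  # modest lipids on record: stay unflagged
            labs.append(_lab(pid, cad - dt.timedelta(days=200), Analyte.LDL, 3.0))
        elif i < 15:  # high value but before the laboratory window opens
            labs.append(_lab(pid, dt.date(1999, 6, 1), Analyte.LDL, 9.9))

    # ---- not premature (25617) ------------------------------------------
    n_rest = N_TOTAL - N_PREMATURE
    n_low_stenosis = 500
    for i in range(n_rest):
        pid = f"FN{i:05d}"
        male = i % 100 < 62
        cad = _cad_date(i)
        if i < n_low_stenosis:
            # young, but stenosis below the angiographic CAD definition
            age = 48.0 if male else 54.0
            stenosis = 40.0
        else:
            age = (65.0 if male else 69.0) + (i % 9)
            stenosis = 80.0
        patients.append(PatientRecord(
            patient_id=pid,
            sex=Sex.MALE if male else Sex.FEMALE,
            birth_date=_birth_for_age(cad, age),
            cad_date=cad,
            max_stenosis_pct=stenosis,
            family_history_early_cad=(i % 2 == 0),
            smoking=Smoking.CURRENT if i % 6 == 0 else Smoking.NON_SMOKER,
        ))

    return patients, labs


# ---------------------------------------------------------------------------
# Stochastic generator


class LognormalSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    loc: float  # mean of log-values
    scale: float = Field(gt=0)  # sd of log-values


class SimParams(BaseModel):
    """Knobs of the stochastic cohort generator.

    Defaults emulate the validation cohort: ~62% male, angiography ages
    centred in the mid-60s, roughly one premature-CAD patient in ten, and
    an overall latent-FH prevalence of 2% concentrated among high-LDL
    patients.  FH-positive patients draw LDL-C from the elevated
    log-normal and report family history far more often.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=1000, gt=0)
    male_fraction: float = Field(default=0.62, ge=0, le=1)
    age_mean_male: float = 65.6
    age_mean_female: float = 69.4
    age_sd: float = Field(default=9.0, gt=0)
    fraction_premature: float = Field(default=0.095, ge=0, le=1)
    true_fh_prevalence: float = Field(default=0.02, ge=0, le=1)
    ldl_fh: LognormalSpec = LognormalSpec(loc=math.log(5.5), scale=0.18)
    ldl_non_fh: LognormalSpec = LognormalSpec(loc=math.log(3.1), scale=0.28)
    tg: LognormalSpec = LognormalSpec(loc=math.log(1.5), scale=0.5)
    family_history_fh: float = Field(default=0.80, ge=0, le=1)
    family_history_non_fh: float = Field(default=0.35, ge=0, le=1)
    secondary_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "esrd": 0.005, "medication": 0.005, "cholestasis": 0.002,
        }
    )
    labs_per_patient: float = Field(default=3.0, gt=0)
    seed: int = 0


def simulate_cohort(
    params: SimParams,
) -> tuple[list[PatientRecord], list[LabMeasurement], pd.DataFrame]:
    """Draw a seeded cohort with a latent FH state per patient.

    Returns registry rows, laboratory rows, and the latent truth table
    (``patient_id``, ``fh``).  Identical parameters (including seed)
    reproduce the output exactly.
    """
    rng = np.random.default_rng(params.seed)
    patients: list[PatientRecord] = []
    labs: list[LabMeasurement] = []
    truth_rows = []
    flag_names = {
        "esrd": SecondaryFlag.ESRD,
        "medication": SecondaryFlag.OFFENDING_MEDICATION,
        "cholestasis": SecondaryFlag.CHOLESTASIS,
        "nephrotic_syndrome": SecondaryFlag.NEPHROTIC_SYNDROME,
    }

    for i in range(params.n_patients):
        pid = f"S{i:06d}"
        male = rng.random() < params.male_fraction
        sex = Sex.MALE if male else Sex.FEMALE
        cutoff = 55.0 if male else 60.0
        mean_age = params.age_mean_male if male else params.age_mean_female
        if rng.random() < params.fraction_premature:
            age = float(rng.uniform(35.0, cutoff - 0.5))
        else:
            age = float(np.clip(rng.normal(mean_age, params.age_sd), cutoff + 0.5, 95.0))
        fh = bool(rng.random() < params.true_fh_prevalence)
        cad = dt.date(2007, 1, 1) + dt.timedelta(days=int(rng.integers(0, 4018)))
        fam_p = params.family_history_fh if fh else params.family_history_non_fh
        flags = frozenset(
            flag_names[name]
            for name, rate in params.secondary_rates.items()
            if name in flag_names and rng.random() < rate
        )
        patients.append(PatientRecord(
            patient_id=pid,
            sex=sex,
            birth_date=_birth_for_age(cad, age),
            cad_date=cad,
            max_stenosis_pct=round(float(rng.uniform(20.0, 95.0)), 1),
            family_history_early_cad=bool(rng.random() < fam_p),
            diabetes_dx=bool(rng.random() < 0.2),
            hypertension_dx=bool(rng.random() < 0.6),
            smoking=Smoking(
                ["non-smoker", "ex-smoker", "current"][int(rng.integers(0, 3))]
            ),
            bmi=round(float(np.clip(rng.normal(29.0, 5.0), 17.0, 55.0)), 1),
            secondary_flags=flags,
        ))
        truth_rows.append({"patient_id": pid, "fh": fh})

        ldl_spec = params.ldl_fh if fh else params.ldl_non_fh
        n_labs = int(rng.poisson(params.labs_per_patient)) + 1
        for _ in range(n_labs):
            # mix of pre- and post-CAD draws across the laboratory window
            offset = int(rng.integers(-2500, 400))
            day = cad + dt.timedelta(days=offset)
            day = max(day, dt.date(2000, 1, 1))
            ldl = float(rng.lognormal(ldl_spec.loc, ldl_spec.scale))
            # post-CAD values reflect treatment
            if day > cad:
                ldl *= float(rng.uniform(0.4, 0.8))
            hdl = float(np.clip(rng.normal(1.3, 0.25), 0.5, 3.0))
            tg = float(rng.lognormal(params.tg.loc, params.tg.scale))
            labs.append(_lab(pid, day, Analyte.LDL, ldl))
            labs.append(_lab(pid, day, Analyte.TC, ldl + hdl + tg / 2.2))
            labs.append(_lab(pid, day, Analyte.TG, tg))

    return patients, labs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Screen evaluation against latent truth


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion of the screen's FH call against the latent state,
    restricted to premature-CAD patients (the tool's target population)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]


def evaluate_screen(report: ScreeningReport, truth: pd.DataFrame) -> EvaluationResult:
    """Score the screen's probable/definite-FH call against latent truth."""
    truth_map = dict(zip(truth["patient_id"], truth["fh"]))
    missing = [
        d.patient.patient_id
        for d in report.decisions
        if d.patient.patient_id not in truth_map
    ]
    if missing:
        raise ValueError(
            f"truth table missing {len(missing)} patient(s), e.g. {missing[0]!r}"
        )
    tp = fp = tn = fn = 0
    for d in report.decisions:
        if not d.premature_cad:
            continue
        called = d.dlcn is not None and d.dlcn.category.value in ("probable", "definite")
        actual = bool(truth_map[d.patient.patient_id])
        if called and actual:
            tp += 1
        elif called:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return EvaluationResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
    )
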