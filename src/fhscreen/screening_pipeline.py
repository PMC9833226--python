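"""The automated FH case-finding pipeline.

Stage order mirrors the clinical procedure the tool automates:

1. premature-CAD filter — angiographic CAD (stenosis strictly above 50%)
   diagnosed before age 55 in men / 60 in women;
2. lipid-history flag — highest pre-CAD TC >= 8 mmol/l or LDL-C >= 5
   mmol/l anywhere in the laboratory window;
3. secondary-cause exclusion — apparent non-genetic explanations for the
   hypercholesterolemia (renal disease, uncontrolled diabetes,
   hypothyroidism, offending drugs, cholestasis, severe
   hypertriglyceridemia) remove a patient from FH analysis;
4. DLCN scoring of the survivors, with flow-chart accounting at every
   stage and a per-patient decision log for auditability.

Genetic-testing status is tallied alongside: founder-panel results
recorded in the registry feed the DLCN DNA item (they are known to the
tool at screening time), whereas gene-panel results are follow-up
investigations counted in the testing flow without reclassifying the
score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cohort_model import (
    Analyte,
    CohortConfig,
    GeneticResult,
    GeneticTestType,
    LabMeasurement,
    PatientRecord,
    SecondaryFlag,
    Sex,
    derive_diabetes,
    derive_hypertension,
)
from .dlcn_engine import DlcnCategory, DlcnInput, DlcnResult, dlcn_points
from .lipid_engine import LipidSummary, goal_attained, summarize_lipids


class ExclusionReason(str, enum.Enum):
    NEPHROTIC_OR_ESRD = "nephrotic_or_esrd"
    UNCONTROLLED_DIABETES = "uncontrolled_diabetes"
    HYPOTHYROIDISM = "hypothyroidism"
    MEDICATION = "medication"
    CHOLESTASIS = "cholestasis"
    HYPERTRIGLYCERIDEMIA = "hypertriglyceridemia"


# deterministic report order for the reasons set
_REASON_ORDER = list(ExclusionReason)


@dataclass(frozen=True)
class ExclusionResult:
    excluded: bool
    reasons: tuple[ExclusionReason, ...]

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag must match non-emptiness of reasons")


@dataclass
class PatientDecision:
    """Stage-by-stage outcome for one patient, with triggering values."""

    patient: PatientRecord
    age_at_cad: float
    premature_cad: bool
    summary: Optional[LipidSummary] = None
    flagged: bool = False
    exclusion: Optional[ExclusionResult] = None
    dlcn: Optional[DlcnResult] = None
    notes: list[str] = field(default_factory=list)

    @property
    def analyzed(self) -> bool:
        return self.flagged and self.exclusion is not None and not self.exclusion.excluded


@dataclass
class ScreeningReport:
    """Per-patient decisions plus the study flow-chart counts."""

    decisions: list[PatientDecision]
    n_total: int
    n_premature_cad: int
    n_flagged: int
    n_excluded: int
    n_analyzed: int
    n_unlikely: int
    n_possible: int
    n_probable: int
    n_definite: int
    n_probable_or_definite: int
    n_genetically_tested: dict[str, int]
    n_pathogenic: int
    n_cascade_referred: int
    n_family_history_unknown: int
    log: list[str] = field(default_factory=list)

    def flow_dict(self) -> dict[str, object]:
        return {
            "n_total": self.n_total,
            "n_premature_cad": self.n_premature_cad,
            "n_flagged": self.n_flagged,
            "n_excluded": self.n_excluded,
            "n_analyzed": self.n_analyzed,
            "n_unlikely": self.n_unlikely,
            "n_possible": self.n_possible,
            "n_probable": self.n_probable,
            "n_definite": self.n_definite,
            "n_probable_or_definite": self.n_probable_or_definite,
            "n_genetically_tested": dict(self.n_genetically_tested),
            "n_pathogenic": self.n_pathogenic,
            "n_cascade_referred": self.n_cascade_referred,
        }


def is_premature_cad(
    sex: Sex,
    age_at_cad: float,
    max_stenosis_pct: float,
    config: CohortConfig | None = None,
) -> bool:
    """Premature angiographic CAD: lumen-diameter reduction strictly above
    the cutoff (default 50%) before age 55 (men) / 60 (women), strict."""
    cfg = config or CohortConfig()
    if max_stenosis_pct <= cfg.stenosis_cutoff:
        return False
    cutoff = cfg.male_age_cutoff if sex is Sex.MALE else cfg.female_age_cutoff
    return age_at_cad < cutoff


def meets_lipid_criterion(
    summary: LipidSummary, config: CohortConfig | None = None
) -> bool:
    """Severe-hypercholesterolemia flag on the pre-CAD history.

    Inclusive comparison (>=) by default: the study counted patients at
    TC >= 8 / LDL-C >= 5 mmol/l.  Set ``threshold_inclusive=false`` for the
    strict reading.
    """
    cfg = config or CohortConfig()

    def over(value: Optional[float], threshold: float) -> bool:
        if value is None:
            return False
        return value >= threshold if cfg.threshold_inclusive else value > threshold

    return over(summary.max_tc_pre_cad, cfg.tc_threshold) or over(
        summary.max_ldl_pre_cad, cfg.ldl_threshold
    )


def secondary_exclusions(
    patient: PatientRecord,
    labs: Sequence[LabMeasurement],
    summary: LipidSummary,
    config: CohortConfig | None = None,
) -> ExclusionResult:
    """Detect apparent secondary causes of hypercholesterolemia.

    All applicable reasons are reported, not just the first, so a referral
    decision can be audited.  Missing laboratory evidence (e.g. no TSH ever
    measured) never excludes.  Fasting status is not recorded in the lab
    table, so every TG value is eligible for the hypertriglyceridemia rule.
    """
    cfg = config or CohortConfig()
    mine = [m for m in labs if m.patient_id == patient.patient_id]
    reasons: list[ExclusionReason] = []

    if (SecondaryFlag.NEPHROTIC_SYNDROME in patient.secondary_flags
            or SecondaryFlag.ESRD in patient.secondary_flags):
        reasons.append(ExclusionReason.NEPHROTIC_OR_ESRD)
    if any(m.analyte is Analyte.HBA1C and m.value > cfg.hba1c_uncontrolled for m in mine):
        reasons.append(ExclusionReason.UNCONTROLLED_DIABETES)
    if any(m.analyte is Analyte.TSH and m.value > cfg.tsh_cutoff for m in mine):
        reasons.append(ExclusionReason.HYPOTHYROIDISM)
    if SecondaryFlag.OFFENDING_MEDICATION in patient.secondary_flags:
        reasons.append(ExclusionReason.MEDICATION)
    if SecondaryFlag.CHOLESTASIS in patient.secondary_flags:
        reasons.append(ExclusionReason.CHOLESTASIS)
    if any(m.analyte is Analyte.TG and m.value > cfg.tg_exclusion for m in mine):
        reasons.append(ExclusionReason.HYPERTRIGLYCERIDEMIA)

    ordered = tuple(sorted(reasons, key=_REASON_ORDER.index))
    return ExclusionResult(excluded=bool(ordered), reasons=ordered)


def dlcn_input_for(
    patient: PatientRecord,
    summary: LipidSummary,
    config: CohortConfig | None = None,
    premature_cad: bool = True,
) -> DlcnInput:
    """Assemble the DLCN scoring facts available to the screening tool.

    Unknown family history scores as absent (conservative).  The LDL-C
    used is the highest pre-CAD value as recorded; a pretreatment
    multiplier is applied only when configured (off by default).  DNA
    points come from founder-panel results recorded in the registry —
    follow-up gene-panel findings do not feed the score.
    """
    cfg = config or CohortConfig()
    ldl = summary.max_ldl_pre_cad
    if ldl is not None and cfg.ldl_pretreatment_multiplier is not None:
        ldl = ldl * cfg.ldl_pretreatment_multiplier
    g = patient.genetic_test
    dna = bool(
        g is not None
        and g.tested
        and g.result is GeneticResult.PATHOGENIC
        and g.test_type is GeneticTestType.FOUNDER_PANEL
    )
    return DlcnInput(
        family_history_early_cad=bool(patient.family_history_early_cad),
        premature_cad=premature_cad,
        premature_other_vascular=patient.premature_other_vascular,
        xanthoma=patient.xanthoma,
        arcus_before_45=patient.arcus_before_45,
        ldl_for_scoring=ldl,
        dna_pathogenic=dna,
    )


def run_screen(
    registry: Sequence[PatientRecord],
    labs: Sequence[LabMeasurement],
    config: CohortConfig | None = None,
) -> ScreeningReport:
    """Run the full screen and tabulate the flow chart.

    Deterministic and row-order independent; an empty cohort yields an
    all-zero report.
    """
    cfg = config or CohortConfig()
    labs_by_patient: dict[str, list[LabMeasurement]] = {}
    for m in labs:
        labs_by_patient.setdefault(m.patient_id, []).append(m)

    decisions: list[PatientDecision] = []
    log: list[str] = []
    n_premature = n_flagged = n_excluded = 0
    n_by_cat = {c: 0 for c in DlcnCategory}
    n_tested = {"possible": 0, "probable_definite": 0}
    n_pathogenic = 0
    n_cascade = 0
    n_fh_unknown = 0

    for p in sorted(registry, key=lambda r: r.patient_id):
        age = p.age_at_cad
        premature = is_premature_cad(p.sex, age, p.max_stenosis_pct, cfg)
        d = PatientDecision(patient=p, age_at_cad=age, premature_cad=premature)
        decisions.append(d)
        if p.family_history_early_cad is None:
            n_fh_unknown += 1
        if not premature:
            d.notes.append(
                f"premature-CAD: no (age {age:.1f}, stenosis {p.max_stenosis_pct:g}%)"
            )
            continue
        n_premature += 1
        mine = labs_by_patient.get(p.patient_id, [])
        d.summary = summarize_lipids(mine, p.cad_date, cfg)
        d.flagged = meets_lipid_criterion(d.summary, cfg)
        d.notes.append(
            "lipid flag: {} (max TC {}, max LDL {})".format(
                "yes" if d.flagged else "no",
                d.summary.max_tc_pre_cad, d.summary.max_ldl_pre_cad,
            )
        )
        if not d.flagged:
            continue
        n_flagged += 1
        d.exclusion = secondary_exclusions(p, mine, d.summary, cfg)
        if d.exclusion.excluded:
            n_excluded += 1
            d.notes.append(
                "excluded: " + ",".join(r.value for r in d.exclusion.reasons)
            )
            continue
        d.dlcn = dlcn_points(dlcn_input_for(p, d.summary, cfg, premature_cad=True))
        n_by_cat[d.dlcn.category] += 1
        d.notes.append(f"DLCN total {d.dlcn.total} -> {d.dlcn.category.value}")
        if d.dlcn.category is DlcnCategory.UNLIKELY:
            log.append(
                f"anomaly: analyzed patient {p.patient_id} scored "
                f"{d.dlcn.total} (<3) despite passing the lipid flag"
            )
        group = (
            "probable_definite"
            if d.dlcn.category in (DlcnCategory.PROBABLE, DlcnCategory.DEFINITE)
            else "possible"
        )
        g = p.genetic_test
        if g is not None and g.tested:
            n_tested[group] += 1
            if group == "probable_definite" and g.result is GeneticResult.PATHOGENIC:
                n_pathogenic += 1
        if p.cascade_referred:
            n_cascade += 1

    n_analyzed = n_flagged - n_excluded
    if n_fh_unknown:
        log.append(f"family history unknown for {n_fh_unknown} patients (scored as absent)")

    return ScreeningReport(
        decisions=decisions,
        n_total=len(registry),
        n_premature_cad=n_premature,
        n_flagged=n_flagged,
        n_excluded=n_excluded,
        n_analyzed=n_analyzed,
        n_unlikely=n_by_cat[DlcnCategory.UNLIKELY],
        n_possible=n_by_cat[DlcnCategory.POSSIBLE],
        n_probable=n_by_cat[DlcnCategory.PROBABLE],
        n_definite=n_by_cat[DlcnCategory.DEFINITE],
        n_probable_or_definite=n_by_cat[DlcnCategory.PROBABLE] + n_by_cat[DlcnCategory.DEFINITE],
        n_genetically_tested=n_tested,
        n_pathogenic=n_pathogenic,
        n_cascade_referred=n_cascade,
        n_family_history_unknown=n_fh_unknown,
        log=log,
    )


def flow_percentages(report: ScreeningReport) -> dict[str, float]:
    """Derived flow quantities on the scale a study report prints them.

    Percentages follow the reporting precision of the source flow chart:
    one decimal for the sub-percent share of all angiographies, whole
    percents elsewhere; the case ratio is the rounded denominator of
    "1 : N" among premature-CAD patients.
    """
    r = report
    out: dict[str, float] = {}
    if r.n_total:
        out["pct_flagged_of_total"] = round(100 * r.n_flagged / r.n_total, 1)
    if r.n_premature_cad:
        out["pct_flagged_of_premature"] = round(100 * r.n_flagged / r.n_premature_cad)
        out["pct_probable_definite_of_premature"] = round(
            100 * r.n_probable_or_definite / r.n_premature_cad
        )
    if r.n_flagged:
        out["pct_excluded_of_flagged"] = round(100 * r.n_excluded / r.n_flagged)
        out["pct_probable_definite_of_flagged"] = round(
            100 * r.n_probable_or_definite / r.n_flagged
        )
    if r.n_analyzed:
        out["pct_probable_definite_of_analyzed"] = round(
            100 * r.n_probable_or_definite / r.n_analyzed
        )
    if r.n_probable_or_definite:
        out["fh_ratio_denominator_in_premature"] = round(
            r.n_premature_cad / r.n_probable_or_definite
        )
        tested_pd = r.n_genetically_tested.get("probable_definite", 0)
        out["pct_probable_definite_tested"] = round(
            100 * tested_pd / r.n_probable_or_definite
        )
        out["pct_probable_definite_untested"] = round(
            100 * (r.n_probable_or_definite - tested_pd) / r.n_probable_or_definite
        )
        if tested_pd:
            out["pct_tested_probable_definite_pathogenic"] = round(
                100 * r.n_pathogenic / tested_pd
            )
    return out


def decisions_frame(report: ScreeningReport, labs: Sequence[LabMeasurement],
                    config: CohortConfig | None = None) -> pd.DataFrame:
    """Flatten per-patient decisions into the analysis table.

    One row per patient with stage outcomes, lipid extrema, DLCN items and
    the derived risk factors — the input for baseline-characteristics
    tables and group statistics.
    """
    cfg = config or CohortConfig()
    labs_by_patient: dict[str, list[LabMeasurement]] = {}
    for m in labs:
        labs_by_patient.setdefault(m.patient_id, []).append(m)
    rows = []
    for d in report.decisions:
        p = d.patient
        s = d.summary
        g = p.genetic_test
        rows.append({
            "patient_id": p.patient_id,
            "sex": p.sex.value,
            "age_at_cad": round(d.age_at_cad, 2),
            "premature_cad": d.premature_cad,
            "flagged": d.flagged,
            "excluded": bool(d.exclusion.excluded) if d.exclusion else False,
            "exclusion_reasons": ";".join(r.value for r in d.exclusion.reasons) if d.exclusion else "",
            "analyzed": d.analyzed,
            "max_tc_pre_cad": s.max_tc_pre_cad if s else None,
            "max_ldl_pre_cad": s.max_ldl_pre_cad if s else None,
            "min_ldl_post_cad": s.min_ldl_post_cad if s else None,
            "ldl_goal_attained": goal_attained(s, cfg) if s else False,
            "dlcn_total": d.dlcn.total if d.dlcn else None,
            "dlcn_category": d.dlcn.category.value if d.dlcn else "",
            "family_history_early_cad": bool(p.family_history_early_cad),
            "diabetes": derive_diabetes(p, labs_by_patient.get(p.patient_id, []), cfg),
            "hypertension": derive_hypertension(p, cfg),
            "smoking": p.smoking.value,
            "bmi": p.bmi,
            "lld_status": p.lld_status.value,
            "genetic_tested": bool(g.tested) if g else False,
            "genetic_result": g.result.value if g and g.result else "",
            "cascade_referred": p.cascade_referred,
            "notes": " | ".join(d.notes),
        })
    return pd.DataFrame(rows)
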