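"""Dutch Lipid Clinic Network (DLCN) scoring and FH category assignment.

The DLCN criteria assign points for family history of premature coronary
disease, personal premature vascular disease, physical stigmata of lipid
accumulation, the (untreated) LDL-C level, and a demonstrated functional
mutation; the total maps to a diagnostic category:

    >=9  definite FH       6-8  probable FH
    3-5  possible FH       0-2  unlikely

Registry-based case-finding cannot observe everything the full criteria
ask for, so this engine carries the screening tool's adaptations: physical
findings (tendon xanthomata, arcus cornealis before 45) default to absent
when not systematically recorded, the family-history item is the single
registry flag "family history of early CAD" worth 1 point (the registry
does not encode relatives' lipid levels or affected children), and the
LDL-C used for scoring is the highest pre-CAD value with no correction
for lipid-lowering treatment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .cohort_model import FounderVariant


class DlcnCategory(str, enum.Enum):
    UNLIKELY = "unlikely"
    POSSIBLE = "possible"
    PROBABLE = "probable"
    DEFINITE = "definite"


@dataclass(frozen=True)
class DlcnInput:
    """The facts the DLCN items are scored from."""

    family_history_early_cad: bool = False
    premature_cad: bool = False
    premature_other_vascular: bool = False
    xanthoma: bool = False
    arcus_before_45: bool = False
    ldl_for_scoring: Optional[float] = None  # mmol/l
    dna_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.ldl_for_scoring is not None and self.ldl_for_scoring <= 0:
            raise ValueError("ldl_for_scoring must be positive when present")


@dataclass(frozen=True)
class DlcnResult:
    points_family: int
    points_clinical: int
    points_physical: int
    points_ldl: int
    points_dna: int
    total: int
    category: DlcnCategory


def ldl_points(ldl: Optional[float]) -> int:
    """LDL-C band points: >=8.5 -> 8, 6.5-8.4 -> 5, 5.0-6.4 -> 3,
    4.0-4.9 -> 1, below 4.0 or unmeasured -> 0."""
    if ldl is None:
        return 0
    if ldl >= 8.5:
        return 8
    if ldl >= 6.5:
        return 5
    if ldl >= 5.0:
        return 3
    if ldl >= 4.0:
        return 1
    return 0


def classify_dlcn(total: int) -> DlcnCategory:
    """Map a DLCN total to its diagnostic category (breakpoints 3, 6, 9)."""
    if total < 0:
        raise ValueError("DLCN total cannot be negative")
    if total >= 9:
        return DlcnCategory.DEFINITE
    if total >= 6:
        return DlcnCategory.PROBABLE
    if total >= 3:
        return DlcnCategory.POSSIBLE
    return DlcnCategory.UNLIKELY


def dlcn_points(inp: DlcnInput) -> DlcnResult:
    """Score all five DLCN item groups and classify the total."""
    family = 1 if inp.family_history_early_cad else 0
    clinical = (2 if inp.premature_cad else 0) + (1 if inp.premature_other_vascular else 0)
    physical = (6 if inp.xanthoma else 0) + (4 if inp.arcus_before_45 else 0)
    ldl = ldl_points(inp.ldl_for_scoring)
    dna = 8 if inp.dna_pathogenic else 0
    total = family + clinical + physical + ldl + dna
    return DlcnResult(
        points_family=family,
        points_clinical=clinical,
        points_physical=physical,
        points_ldl=ldl,
        points_dna=dna,
        total=total,
        category=classify_dlcn(total),
    )


#: The four Finnish LDLR founder mutations tested by the regional panel.
_FOUNDER_CATALOG: tuple[FounderVariant, ...] = (
    FounderVariant(name="FH-Helsinki", gene="LDLR", hgvs="g.39215_47749del8535"),
    FounderVariant(name="FH-North-Karelia", gene="LDLR", hgvs="c.925_931delCCCATCA, p.(Pro309Lysfs)"),
    FounderVariant(name="FH-Pori", gene="LDLR", hgvs="c.1202T > A, p.(Leu401His)"),
    FounderVariant(name="FH-Turku", gene="LDLR", hgvs="c.2531G > A, p.(Gly844Asp)"),
)


def founder_catalog() -> list[FounderVariant]:
    """The founder-variant panel: four LDLR mutations enriched in the
    Finnish population, which together account for the majority of Finnish
    FH cases."""
    return list(_FOUNDER_CATALOG)
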