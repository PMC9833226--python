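"""LDL-C computation and longitudinal lipid-history summarization.

The screening rules key off a patient's *worst* pre-CAD lipid values —
the highest total cholesterol and LDL-C recorded between the start of the
laboratory window (2000-01-01 by default) and the baseline angiography —
and the *best* post-CAD LDL-C, used for treatment-goal assessment.  LDL-C
arrives either as a directly measured value or is estimated with the
Friedewald equation (LDL = TC − HDL − TG/2.2, mmol/l), which is invalid at
high triglycerides (default TG > 4.5 mmol/l).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort_model import Analyte, CohortConfig, LabMeasurement, LdlMethod

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LipidSummary:
    """Per-patient lipid-history extrema around the baseline CAD date.

    Pre-CAD extrema are taken over the half-open window
    ``[lab_window_start, cad_date)``; the post-CAD minimum over dates
    strictly after ``cad_date``.  Fields are ``None`` when no qualifying
    measurement exists.
    """

    max_tc_pre_cad: Optional[float] = None
    max_tc_date: Optional[dt.date] = None
    max_ldl_pre_cad: Optional[float] = None
    max_ldl_date: Optional[dt.date] = None
    max_tg: Optional[float] = None
    max_tg_date: Optional[dt.date] = None
    min_ldl_post_cad: Optional[float] = None
    min_ldl_post_date: Optional[dt.date] = None


def friedewald_ldl(
    tc: float, hdl: float, tg: float, config: CohortConfig | None = None
) -> Optional[float]:
    """Estimate LDL-C (mmol/l) as TC − HDL − TG/2.2.

    Returns ``None`` when TG exceeds the validity limit.  A negative
    estimate (possible with extreme inputs) is floored at 0 with a warning
    rather than propagated.
    """
    cfg = config or CohortConfig()
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("lipid concentrations must be nonnegative")
    if tg > cfg.friedewald_tg_max:
        return None
    ldl = tc - hdl - tg / 2.2
    if ldl < 0:
        logger.warning(
            "Friedewald estimate %.2f mmol/l negative (TC %.2f, HDL %.2f, TG %.2f); floored at 0",
            ldl, tc, hdl, tg,
        )
        return 0.0
    return ldl


@dataclass(frozen=True)
class ResolvedLdl:
    value: float
    method: LdlMethod
    date: dt.date


def resolve_ldl(
    labs_on_day: Sequence[LabMeasurement],
    config: CohortConfig | None = None,
    prefer: str = "max",
) -> Optional[ResolvedLdl]:
    """Resolve one day's LDL-C from the measurements taken that day.

    A recorded LDL value wins verbatim (its method label defaults to the
    assay era implied by the date: Friedewald up to the era-end date,
    direct thereafter).  Otherwise a complete same-day TC+HDL+TG triple
    yields a Friedewald estimate.  An incomplete day resolves to nothing —
    that is missing data, not an error.

    ``prefer`` breaks same-day duplicates: "max" when hunting the highest
    pre-CAD value, "min" when hunting the post-CAD best.
    """
    cfg = config or CohortConfig()
    if prefer not in ("max", "min"):
        raise ValueError("prefer must be 'max' or 'min'")
    pick = max if prefer == "max" else min
    if not labs_on_day:
        return None
    day = labs_on_day[0].date
    if any(m.date != day for m in labs_on_day):
        raise ValueError("resolve_ldl expects measurements from a single day")

    direct = [m for m in labs_on_day if m.analyte is Analyte.LDL]
    if direct:
        m = pick(direct, key=lambda r: r.value)
        method = m.ldl_method
        if method is LdlMethod.NA:
            method = (
                LdlMethod.FRIEDEWALD if day <= cfg.friedewald_era_end else LdlMethod.DIRECT
            )
        return ResolvedLdl(value=m.value, method=method, date=day)

    by_analyte: dict[Analyte, float] = {}
    for m in labs_on_day:
        if m.analyte in (Analyte.TC, Analyte.HDL, Analyte.TG):
            prev = by_analyte.get(m.analyte)
            by_analyte[m.analyte] = m.value if prev is None else pick(prev, m.value)
    if not all(a in by_analyte for a in (Analyte.TC, Analyte.HDL, Analyte.TG)):
        return None
    est = friedewald_ldl(
        by_analyte[Analyte.TC], by_analyte[Analyte.HDL], by_analyte[Analyte.TG], cfg
    )
    if est is None:
        return None
    return ResolvedLdl(value=est, method=LdlMethod.FRIEDEWALD, date=day)


def _ldl_series(
    labs: Sequence[LabMeasurement], config: CohortConfig, prefer: str = "max"
) -> list[ResolvedLdl]:
    by_day: dict[dt.date, list[LabMeasurement]] = {}
    for m in labs:
        by_day.setdefault(m.date, []).append(m)
    out = []
    for day in sorted(by_day):
        r = resolve_ldl(by_day[day], config, prefer=prefer)
        if r is not None:
            out.append(r)
    return out


def summarize_lipids(
    labs: Sequence[LabMeasurement],
    cad_date: dt.date,
    config: CohortConfig | None = None,
) -> LipidSummary:
    """Reduce one patient's laboratory history to the screening extrema.

    The result is order-independent: measurements may arrive in any order.
    LDL-C values are taken as recorded where a direct/recorded LDL row
    exists and Friedewald-derived from same-day triples otherwise.
    """
    cfg = config or CohortConfig()
    window = [m for m in labs if m.date >= cfg.lab_window_start]
    pre = [m for m in window if m.date < cad_date]
    post_days = [m for m in labs if m.date > cad_date]

    def _extremum(rows, analyte, fn):
        vals = [(m.value, m.date) for m in rows if m.analyte is analyte]
        if not vals:
            return None, None
        v, d = fn(vals, key=lambda t: t[0])
        return v, d

    max_tc, tc_date = _extremum(pre, Analyte.TC, max)
    max_tg, tg_date = _extremum(pre, Analyte.TG, max)

    pre_ldl = _ldl_series(pre, cfg)
    if pre_ldl:
        best = max(pre_ldl, key=lambda r: r.value)
        max_ldl, ldl_date = best.value, best.date
    else:
        max_ldl, ldl_date = None, None

    post_ldl = _ldl_series(post_days, cfg, prefer="min")
    if post_ldl:
        best_post = min(post_ldl, key=lambda r: r.value)
        min_ldl, min_date = best_post.value, best_post.date
    else:
        min_ldl, min_date = None, None

    return LipidSummary(
        max_tc_pre_cad=max_tc, max_tc_date=tc_date,
        max_ldl_pre_cad=max_ldl, max_ldl_date=ldl_date,
        max_tg=max_tg, max_tg_date=tg_date,
        min_ldl_post_cad=min_ldl, min_ldl_post_date=min_date,
    )


def goal_attained(summary: LipidSummary, config: CohortConfig | None = None) -> bool:
    """Post-CAD LDL-C treatment goal (<=1.8 mmol/l by default) ever reached.

    Absent post-CAD LDL means no evidence of attainment, hence False.
    """
    cfg = config or CohortConfig()
    return summary.min_ldl_post_cad is not None and summary.min_ldl_post_cad <= cfg.ldl_goal
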