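"""Independent brute-force oracles used by the test suite.

Deliberately naive re-derivations of the screening rules and test
statistics, sharing no code with the package beyond the record types.
"""

from __future__ import annotations

import datetime as dt
import itertools
from collections import Counter

import numpy as np


def brute_force_flow(patients, labs, *,
                     tc_threshold=8.0, ldl_threshold=5.0) -> dict:
    """Evaluate every rule independently per patient and tabulate the flow."""
    labs_by_pid = {}
    for m in labs:
        labs_by_pid.setdefault(m.patient_id, []).append(m)

    counts = Counter()
    counts["n_total"] = len(patients)
    for p in patients:
        mine = labs_by_pid.get(p.patient_id, [])
        age = (p.cad_date - p.birth_date).days / 365.25
        cutoff = 55.0 if p.sex.value == "male" else 60.0
        premature = p.max_stenosis_pct > 50.0 and age < cutoff
        if not premature:
            continue
        counts["n_premature_cad"] += 1

        window_start = dt.date(2000, 1, 1)
        pre = [m for m in mine if window_start <= m.date < p.cad_date]
        tcs = [m.value for m in pre if m.analyte.value == "TC"]
        # LDL on a day: recorded value, else Friedewald from a full triple
        ldls = []
        for day in {m.date for m in pre}:
            today = [m for m in pre if m.date == day]
            direct = [m.value for m in today if m.analyte.value == "LDL"]
            if direct:
                ldls.append(max(direct))
                continue
            trip = {
                a: max(m.value for m in today if m.analyte.value == a)
                for a in ("TC", "HDL", "TG")
                if any(m.analyte.value == a for m in today)
            }
            if len(trip) == 3 and trip["TG"] <= 4.5:
                ldls.append(max(trip["TC"] - trip["HDL"] - trip["TG"] / 2.2, 0.0))
        max_tc = max(tcs) if tcs else None
        max_ldl = max(ldls) if ldls else None
        flagged = (max_tc is not None and max_tc >= tc_threshold) or (
            max_ldl is not None and max_ldl >= ldl_threshold
        )
        if not flagged:
            continue
        counts["n_flagged"] += 1

        flags = {f.value for f in p.secondary_flags}
        excluded = (
            bool(flags & {"nephrotic_syndrome", "esrd", "cholestasis",
                          "offending_medication"})
            or any(m.analyte.value == "HbA1c" and m.value > 70 for m in mine)
            or any(m.analyte.value == "TSH" and m.value > 10 for m in mine)
            or any(m.analyte.value == "TG" and m.value > 10 for m in mine)
        )
        if excluded:
            counts["n_excluded"] += 1
            continue
        counts["n_analyzed"] += 1

        g = p.genetic_test
        dna = bool(
            g and g.tested and g.result and g.result.value == "pathogenic_variant"
            and g.test_type and g.test_type.value == "founder_panel"
        )
        total = (
            (1 if p.family_history_early_cad else 0)
            + 2  # premature CAD, established above
            + (1 if p.premature_other_vascular else 0)
            + (6 if p.xanthoma else 0)
            + (4 if p.arcus_before_45 else 0)
            + (8 if dna else 0)
        )
        if max_ldl is not None:
            if max_ldl >= 8.5:
                total += 8
            elif max_ldl >= 6.5:
                total += 5
            elif max_ldl >= 5.0:
                total += 3
            elif max_ldl >= 4.0:
                total += 1
        if total >= 9:
            counts["n_definite"] += 1
        elif total >= 6:
            counts["n_probable"] += 1
        elif total >= 3:
            counts["n_possible"] += 1
        else:
            counts["n_unlikely"] += 1
    return dict(counts)


def exact_mann_whitney_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties)."""
    a, b = list(a), list(b)
    n1, pooled = len(a), sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(c + 1 for c in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    n2 = len(b)
    # two-sided: distance from the null mean
    mean = n1 * n2 / 2
    p = np.mean(np.abs(us - mean) >= abs(u_obs - mean) - 1e-12)
    return float(p)


def pearson_chi2(table) -> tuple[float, int]:
    """Pearson statistic and df from the closed-form definition."""
    t = np.asarray(table, dtype=float)
    rowsum = t.sum(axis=1, keepdims=True)
    colsum = t.sum(axis=0, keepdims=True)
    expected = rowsum @ colsum / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df
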