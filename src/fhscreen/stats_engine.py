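"""Group-comparison statistics for the screened cohort.

Categorical variables are compared with Pearson's chi-square test on the
contingency table, without Yates continuity correction (the dialect used
by common clinical-statistics software, and the one that reproduces the
published group comparisons here).  Continuous variables are compared
with the Mann-Whitney U test: exact enumeration for small untied samples,
otherwise the tie-corrected normal approximation.  Baseline tables report
n (%) for categorical rows, mean (SD) for age and BMI, and median
(Q1-Q3) with linear-interpolation quartiles for lipid levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_EXACT_MAX_N = 20  # combined sample size up to which the exact MW null is used


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of nonnegative integer counts with labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("cell counts must be nonnegative")
        if arr.sum() == 0:
            raise ValueError("contingency table total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def chi_square(table: ContingencyTable | Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(tuple(int(c) for c in row) for row in table))
    arr = table.array
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("chi-square undefined: a row or column sum is zero")
    res = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_two_sided=float(res.pvalue),
        df=int(res.dof),
        method="pearson-chi-square",
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (U reported for sample ``a``).

    Small untied samples (combined n <= 20) use the exact permutation
    null; larger or tied samples use the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "mann-whitney-exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "mann-whitney-normal-approx"
    return TestResult(
        statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=method,
    )


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quartiles of an empty sample are undefined")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def format_p(p: float) -> str:
    """Three-decimal p-values, '<0.001' below 0.0005 (table style)."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


# ---------------------------------------------------------------------------
# Baseline ("Table 1") builder

#: rows of the baseline table: (label, column, kind)
_BASELINE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Gender", "sex", "categorical"),
    ("Age at baseline CAD", "age_at_cad", "continuous-mean"),
    ("TC, mmol/l", "max_tc_pre_cad", "continuous-median"),
    ("LDL-C, mmol/l", "max_ldl_pre_cad", "continuous-median"),
    ("Family history of early CAD", "family_history_early_cad", "binary"),
    ("Hypertension", "hypertension", "binary"),
    ("Diabetes", "diabetes", "binary"),
    ("Smoking", "smoking", "categorical"),
    ("BMI", "bmi", "continuous-mean"),
    ("LLD in use at baseline CAD", "lld_status", "lld"),
    ("LDL-C goal achieved after CAD", "ldl_goal_attained", "binary"),
)


def _split_groups(patients: pd.DataFrame, by: str) -> tuple[str, str, pd.DataFrame, pd.DataFrame]:
    analyzed = patients[patients["analyzed"]]
    if by == "dlcn":
        g1 = analyzed[analyzed["dlcn_category"] == "possible"]
        g2 = analyzed[analyzed["dlcn_category"].isin(["probable", "definite"])]
        return "possible FH", "probable/definite FH", g1, g2
    if by == "genetic":
        g1 = analyzed[~analyzed["genetic_tested"]]
        g2 = analyzed[analyzed["genetic_tested"]]
        return "no genetic testing", "genetic testing", g1, g2
    raise ValueError(f"unknown partition {by!r}; expected 'dlcn' or 'genetic'")


def contingency_from_frame(
    patients: pd.DataFrame, column: str, by: str = "dlcn"
) -> ContingencyTable:
    """Group-by-level count table for one categorical patient variable."""
    name1, name2, g1, g2 = _split_groups(patients, by)
    levels = sorted(set(g1[column].dropna()) | set(g2[column].dropna()), key=str)
    counts = tuple(
        tuple(int((g[column] == lv).sum()) for lv in levels) for g in (g1, g2)
    )
    return ContingencyTable(
        counts=counts,
        row_labels=(name1, name2),
        col_labels=tuple(str(lv) for lv in levels),
    )


def baseline_table(patients: pd.DataFrame, by: str = "dlcn") -> pd.DataFrame:
    """Baseline-characteristics table with a p-value column.

    ``patients`` is the per-patient decision frame; only analyzed patients
    (flagged, not excluded) enter.  ``by`` partitions them by DLCN
    category (possible vs probable/definite) or by genetic-testing status.
    Categorical rows get chi-square p-values, continuous rows Mann-Whitney.
    """
    name1, name2, g1, g2 = _split_groups(patients, by)
    out_rows: list[dict[str, object]] = []

    def add(label: str, v1: str, v2: str, p: str = "") -> None:
        out_rows.append({
            "variable": label,
            f"{name1} (n={len(g1)})": v1,
            f"{name2} (n={len(g2)})": v2,
            "p_value": p,
        })

    for label, col, kind in _BASELINE_ROWS:
        if kind in ("categorical", "binary", "lld"):
            if kind == "binary":
                tables = [(True, label)]
                levels = [True, False]
            elif kind == "lld":
                tables = [("in-use", label)]
                levels = ["in-use", "prescribed-not-used", "none"]
            else:
                levels = sorted(set(g1[col].dropna()) | set(g2[col].dropna()), key=str)
                tables = None
            counts1 = {lv: int((g1[col] == lv).sum()) for lv in levels}
            counts2 = {lv: int((g2[col] == lv).sum()) for lv in levels}
            try:
                tab = ContingencyTable(
                    counts=(
                        tuple(counts1[lv] for lv in levels),
                        tuple(counts2[lv] for lv in levels),
                    )
                )
                p = format_p(chi_square(tab).p_two_sided)
            except ValueError:
                p = ""
            if tables is None:  # multi-level: one sub-row per level
                add(label, "", "", p)
                for lv in levels:
                    add(
                        f"  {lv}",
                        _n_pct(counts1[lv], len(g1)),
                        _n_pct(counts2[lv], len(g2)),
                    )
            else:
                lv, label_out = tables[0]
                add(label_out, _n_pct(counts1[lv], len(g1)), _n_pct(counts2[lv], len(g2)), p)
        else:
            v1 = g1[col].dropna().to_numpy(dtype=float)
            v2 = g2[col].dropna().to_numpy(dtype=float)
            if v1.size == 0 or v2.size == 0:
                add(label, "", "", "")
                continue
            p = format_p(mann_whitney(v1, v2).p_two_sided)
            if kind == "continuous-mean":
                add(
                    label,
                    f"{v1.mean():.1f} ({v1.std(ddof=1):.1f})",
                    f"{v2.mean():.1f} ({v2.std(ddof=1):.1f})",
                    p,
                )
            else:
                q1a, meda, q3a = quartiles(v1)
                q1b, medb, q3b = quartiles(v2)
                add(
                    label,
                    f"{meda:.1f} ({q1a:.1f}-{q3a:.1f})",
                    f"{medb:.1f} ({q1b:.1f}-{q3b:.1f})",
                    p,
                )
    return pd.DataFrame(out_rows)


def _n_pct(n: int, total: int) -> str:
    pct = 100 * n / total if total else 0.0
    return f"{n} ({pct:.1f}%)"
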