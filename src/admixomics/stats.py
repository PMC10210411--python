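"""Contingency statistics and cohort-characteristics tables.

Shared statistical utilities for the ancestry comparison pipeline: Pearson
chi-squared tests on 2x2 and r x c tables, Benjamini-Hochberg adjustment,
and a clinical-characteristics summary table comparing the African-ancestry
(AA) and European-ancestry (EA) groups.

The 2x2 test applies the Yates continuity correction by default; with the
correction on, the test reproduces published cohort-level contrasts computed
from raw counts (see the test suite). The r x c generalisation is
uncorrected, the usual convention for tables larger than 2x2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChiSqResult",
    "two_by_two_chisq",
    "rxc_chisq",
    "bh_adjust",
    "build_cohort_table",
]


@dataclass
class ChiSqResult:
    """Result of a Pearson chi-squared independence test.

    Attributes
    ----------
    observed : ndarray
        The observed count table actually tested (after any degenerate
        row/column removal for r x c input).
    statistic : float
        Pearson chi-squared statistic (continuity-corrected if requested).
    df : int
        Degrees of freedom, ``(r - 1) * (c - 1)``.
    p : float
        Two-sided p-value from the chi-squared reference distribution.
    correction_applied : bool
        Whether the Yates continuity correction was used.
    degenerate : bool
        True when a zero margin forced the conventional ``p = 1`` result.
    """

    observed: np.ndarray
    statistic: float
    df: int
    p: float
    correction_applied: bool
    degenerate: bool = field(default=False)


def _as_count_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("contingency table contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError("contingency table contains negative counts")
    if np.any(arr != np.round(arr)):
        raise ValueError("contingency table entries must be integers")
    return arr


def two_by_two_chisq(a: int, b: int, c: int, d: int, correction: bool = True) -> ChiSqResult:
    """Pearson chi-squared test on the 2x2 table ``[[a, b], [c, d]]``.

    With ``correction=True`` the Yates continuity correction is applied:
    each ``|O - E|`` is reduced by 0.5 but floored at zero, so perfectly
    proportional tables keep a statistic of exactly 0.

    A table with a zero row or column margin carries no information about
    association; by convention it returns ``statistic=0, p=1`` flagged as
    degenerate rather than raising.
    """
    obs = _as_count_table([[a, b], [c, d]])
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        return ChiSqResult(obs, 0.0, 1, 1.0, correction, degenerate=True)
    stat, p, df, _ = sps.chi2_contingency(obs, correction=correction)
    return ChiSqResult(obs, float(stat), int(df), float(p), correction)


def rxc_chisq(table) -> ChiSqResult:
    """Pearson chi-squared test on an r x c table, no continuity correction.

    Rows or columns with a zero margin are dropped with a warning (they
    contribute no expected counts); at least a 2x2 table must remain.
    """
    obs = _as_count_table(table)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        obs = obs[np.ix_(row_ok, col_ok)]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            return ChiSqResult(obs, 0.0, 1, 1.0, False, degenerate=True)
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return ChiSqResult(obs, float(stat), int(df), float(p), correction_applied=False)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs propagate as NaN (with a warning); the remaining values are
    adjusted as a family of their own. Output is elementwise >= input and
    capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() < p.size:
        warnings.warn("NaN p-values propagated unadjusted")
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Cohort characteristics table


def _fmt_cell(n: int, total: int) -> str:
    return f"{n} ({100.0 * n / total:.2f})"


def build_cohort_table(clinical: pd.DataFrame) -> dict:
    """Summarise clinical characteristics by ancestry group with tests.

    Parameters
    ----------
    clinical : DataFrame
        Columns ``patient_id, age, stage, subtype, grade, group`` with
        ``group`` in {"AA", "EA"}.

    Returns
    -------
    dict with keys:

    ``table`` : DataFrame
        Per-characteristic "n (pct)" cells for each group, percentages at
        two decimal places, plus age mean (SD) and median rows.
    ``comparisons`` : dict
        Chi-squared results: stage IV vs other; each subtype level vs rest;
        tumour grade both as high-vs-low excluding unknown and as the full
        low/high/unknown r x c table (the appropriate grouping for grade is
        ambiguous, so both are reported and neither is privileged).
    """
    for colname in ("age", "stage", "subtype", "grade", "group"):
        if colname not in clinical.columns:
            raise ValueError(f"clinical table missing column {colname!r}")
    groups = ("AA", "EA")
    sub = {g: clinical[clinical["group"] == g] for g in groups}
    for g in groups:
        if len(sub[g]) == 0:
            raise ValueError(f"group {g} is empty")
    n = {g: len(sub[g]) for g in groups}

    rows = []
    rows.append(
        {
            "characteristic": "age",
            "level": "mean (SD), median",
            **{
                g: f"{sub[g]['age'].mean():.2f} ({sub[g]['age'].std():.2f}), {sub[g]['age'].median():.2f}"
                for g in groups
            },
        }
    )
    for var, order in (
        ("stage", ["0", "I", "II", "III", "IV"]),
        ("subtype", ["HRpos_HER2neg", "TNBC", "Other"]),
        ("grade", ["low", "high", "unknown"]),
    ):
        for level in order:
            rows.append(
                {
                    "characteristic": var,
                    "level": level,
                    **{g: _fmt_cell(int((sub[g][var] == level).sum()), n[g]) for g in groups},
                }
            )
    table = pd.DataFrame(rows)

    comparisons: dict = {}

    def _level_vs_rest(var: str, level: str):
        k = {g: int((sub[g][var] == level).sum()) for g in groups}
        return two_by_two_chisq(k["AA"], n["AA"] - k["AA"], k["EA"], n["EA"] - k["EA"])

    if clinical["stage"].nunique() > 1:
        comparisons["stage_IV_vs_other"] = _level_vs_rest("stage", "IV")
    else:
        comparisons["stage_IV_vs_other"] = None  # degenerate: single level, skipped
    for level in ("HRpos_HER2neg", "TNBC", "Other"):
        comparisons[f"subtype_{level}_vs_rest"] = _level_vs_rest("subtype", level)

    grade_counts = {
        g: {lv: int((sub[g]["grade"] == lv).sum()) for lv in ("low", "high", "unknown")}
        for g in groups
    }
    comparisons["grade_high_vs_low"] = two_by_two_chisq(
        grade_counts["AA"]["high"],
        grade_counts["AA"]["low"],
        grade_counts["EA"]["high"],
        grade_counts["EA"]["low"],
    )
    comparisons["grade_rxc"] = rxc_chisq(
        [
            [grade_counts["AA"][lv] for lv in ("low", "high", "unknown")],
            [grade_counts["EA"][lv] for lv in ("low", "high", "unknown")],
        ]
    )
    return {"table": table, "comparisons": comparisons}
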