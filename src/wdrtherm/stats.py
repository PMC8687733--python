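"""Group-comparison statistics for cohort summary tables.

A thin, explicit layer reproducing the study's testing policy: normality of
both samples is checked with the D'Agostino–Pearson omnibus test; when both
pass at alpha = 0.05 an unpaired pooled-variance Student t-test is used
(pooled, not Welch — the printed integer degrees of freedom n1 + n2 - 2
identify the variant), otherwise the Mann–Whitney U test.  One-way ANOVA with
Tukey HSD post hoc tests covers the multi-group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "anova_tukey", "ALPHA"]

ALPHA = 0.05
#: D'Agostino–Pearson needs enough samples for the kurtosis test
_NORMALITY_MIN_N = 8


@dataclass(frozen=True)
class GroupComparison:
    test_name: str            # "t" (pooled) or "mann-whitney"
    statistic: float
    dof: float                # t-test dof; NaN for Mann-Whitney
    p_value: float
    normality_passed: tuple[bool, bool]


def compare_groups(a, b, alpha: float = ALPHA) -> GroupComparison:
    """Two-sample comparison with the normality-gated test choice.

    Samples shorter than the omnibus test's minimum (n < 8) fall back to the
    nonparametric branch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")

    def normal(x: np.ndarray) -> bool:
        if x.size < _NORMALITY_MIN_N or np.ptp(x) == 0:
            return False
        return bool(sps.normaltest(x).pvalue > alpha)

    norm = (normal(a), normal(b))
    if all(norm):
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison(
            test_name="t", statistic=float(res.statistic),
            dof=float(a.size + b.size - 2), p_value=float(res.pvalue),
            normality_passed=norm,
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        test_name="mann-whitney", statistic=float(res.statistic),
        dof=math.nan, p_value=float(res.pvalue), normality_passed=norm,
    )


def anova_tukey(groups, alpha: float = ALPHA) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA (F with k-1, N-k dof) plus Tukey HSD pairwise tests.

    Returns (anova_table, tukey_table); the degenerate all-equal case reports
    F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    degenerate = np.ptp(np.concatenate(groups)) == 0
    if degenerate:
        f_stat, p = 0.0, 1.0
    else:
        res = sps.f_oneway(*groups)
        f_stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(f_stat):  # zero within-group variance everywhere
            f_stat, p = 0.0, 1.0
    anova = pd.DataFrame(
        [{"F": f_stat, "dof_between": k - 1, "dof_within": n_total - k, "p": p}]
    )
    tukey = None if degenerate else sps.tukey_hsd(*groups)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pij = 1.0 if tukey is None else float(tukey.pvalue[i, j])
            rows.append({
                "group_a": i, "group_b": j,
                "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p": pij,
                "significant": bool(pij < alpha),
            })
    return anova, pd.DataFrame(rows)
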