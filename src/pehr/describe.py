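"""Table-1-style group comparisons.

Continuous variables are displayed as median (IQR) and compared by t-test
(ANOVA for >2 groups; Wilcoxon rank-sum optional); categorical variables
as n (%) with a chi-square family test chosen from the expected counts:
2x2 tables with all expected counts >= 5 use the continuity-corrected
(Yates) chi-square, 2x2 tables with any expected count < 5 fall back to
Fisher's exact test, and larger tables use the plain Pearson chi-square.
The test actually used is reported per row.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError


def _continuous_row(x_groups: list[np.ndarray], test: str) -> tuple[str, float]:
    if test == "rank-sum":
        if len(x_groups) != 2:
            raise DataValidationError("rank-sum needs exactly 2 groups")
        stat, p = stats.mannwhitneyu(x_groups[0], x_groups[1],
                                     alternative="two-sided")
        return "rank-sum", float(p)
    if len(x_groups) == 2:
        stat, p = stats.ttest_ind(x_groups[0], x_groups[1])
        return "t-test", float(p)
    stat, p = stats.f_oneway(*x_groups)
    return "ANOVA", float(p)


def categorical_test(table: np.ndarray) -> tuple[str, float]:
    """Choose and run the chi-square-family test for a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        return "Fisher", 1.0
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        # a degenerate margin: chi-square undefined; exact test trivially 1
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            return "Fisher", float(p)
        return "Fisher", 1.0
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2):
        if np.any(expected < 5):
            _, p = stats.fisher_exact(table)
            return "Fisher", float(p)
        stat, p, _, _ = stats.chi2_contingency(table, correction=True)
        return "corrected chi-square", float(p)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi-square", float(p)


def compare_groups(data: pd.DataFrame, group_col: str,
                   continuous: Sequence[str] = (),
                   categorical: Sequence[str] = (),
                   continuous_test: str = "t") -> pd.DataFrame:
    """One summary/test row per variable, in Table-1 layout.

    ``continuous_test`` is 't' (default) or 'rank-sum'. Group summaries
    are 'median (q1, q3)' for continuous and 'n (pct)' for categorical
    variables.
    """
    for v in list(continuous) + list(categorical):
        if v not in data.columns:
            raise DataValidationError(f"compare_groups: variable {v!r} absent")
    levels = list(pd.unique(data[group_col]))
    grouped = [data[data[group_col] == g] for g in levels]
    rows = []
    for var in continuous:
        xs = [g[var].dropna().to_numpy(dtype=float) for g in grouped]
        test_name, p = _continuous_row(
            xs, "rank-sum" if continuous_test == "rank-sum" else "t")
        row = {"variable": var, "type": "continuous",
               "test": test_name, "p": p}
        for lev, x in zip(levels, xs):
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            row[f"group_{lev}"] = f"{med:.2f} ({q1:.2f}, {q3:.2f})"
        rows.append(row)
    for var in categorical:
        sub = data[[group_col, var]].dropna()
        table = pd.crosstab(sub[var], sub[group_col]) \
            .reindex(columns=levels, fill_value=0)
        test_name, p = categorical_test(table.to_numpy())
        row = {"variable": var, "type": "categorical",
               "test": test_name, "p": p}
        for lev in levels:
            n_pos = int(sub.loc[sub[group_col] == lev, var].astype(bool).sum())
            n_tot = int((sub[group_col] == lev).sum())
            pct = 100.0 * n_pos / n_tot if n_tot else 0.0
            row[f"group_{lev}"] = f"{n_pos} ({pct:.0f}%)"
        rows.append(row)
    return pd.DataFrame(rows)
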