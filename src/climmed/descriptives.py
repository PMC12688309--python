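"""Descriptive comparisons of the cohort by outcome status.

Continuous variables are summarized as mean (SD) per outcome group and
compared with a two-sample t-test (Welch by default); categorical
variables as counts and percentages per group, compared with Pearson's
chi-squared test on the full contingency table (no continuity
correction). Percentage denominators are the outcome-group totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateGroupError, InvalidArgumentError
from .schema import CATEGORY_LEVELS

__all__ = ["describe_by_outcome", "chi_square_test", "t_test"]


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table.

    Returns ``(statistic, df, p)`` with df = (r−1)(c−1); no Yates
    correction. Requires strictly positive row and column margins.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InvalidArgumentError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise InvalidArgumentError("contingency table counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidArgumentError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def t_test(
    x: np.ndarray, y: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test; Welch (unequal variances) unless ``equal_var``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateGroupError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def describe_by_outcome(
    data: pd.DataFrame,
    outcome: str,
    variables: list[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Build the descriptive comparison table by outcome status.

    One row per categorical level (count, pct per group) or per
    continuous variable (mean, sd per group), plus the test statistic
    and p-value. Percentages are stored unrounded.
    """
    if outcome not in data.columns:
        raise InvalidArgumentError(f"outcome column missing: {outcome!r}")
    groups = {"no": data[data[outcome] == "no"], "yes": data[data[outcome] == "yes"]}
    for label, g in groups.items():
        if g.empty:
            raise DegenerateGroupError(f"outcome group {label!r} is empty")
    rows: list[dict] = []
    for var in variables:
        if var not in data.columns:
            raise InvalidArgumentError(f"variable column missing: {var!r}")
        if var in CATEGORY_LEVELS and var != outcome:
            levels = [
                lv for lv in CATEGORY_LEVELS[var]
                if lv in set(data[var].dropna().unique())
            ]
            table = np.array(
                [
                    [(groups[g][var] == lv).sum() for g in ("no", "yes")]
                    for lv in levels
                ],
                dtype=float,
            )
            stat, df, p = chi_square_test(table)
            for i, lv in enumerate(levels):
                n_no, n_yes = table[i]
                rows.append(
                    {
                        "variable": var,
                        "level": lv,
                        "kind": "categorical",
                        "no_count": int(n_no),
                        "no_pct": 100.0 * n_no / len(groups["no"]),
                        "yes_count": int(n_yes),
                        "yes_pct": 100.0 * n_yes / len(groups["yes"]),
                        "total_count": int(n_no + n_yes),
                        "total_pct": 100.0 * (n_no + n_yes) / len(data),
                        "statistic": stat,
                        "df": df,
                        "p_value": p,
                        "test": "chi-squared",
                    }
                )
        else:
            x = groups["no"][var].dropna().to_numpy(dtype=float)
            y = groups["yes"][var].dropna().to_numpy(dtype=float)
            stat, p = t_test(x, y, equal_var=equal_var)
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "kind": "continuous",
                    "no_mean": float(np.mean(x)),
                    "no_sd": float(np.std(x, ddof=1)),
                    "yes_mean": float(np.mean(y)),
                    "yes_sd": float(np.std(y, ddof=1)),
                    "total_mean": float(data[var].astype(float).mean()),
                    "total_sd": float(data[var].astype(float).std(ddof=1)),
                    "statistic": stat,
                    "p_value": p,
                    "test": "welch-t" if not equal_var else "pooled-t",
                }
            )
    return pd.DataFrame(rows)
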