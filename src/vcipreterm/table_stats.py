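"""Descriptive two-group comparisons for cohort characteristic tables.

Dialects matter for reproducing published tables: 2x2 chi-squares use the
Yates continuity correction, while r x c tables use the plain Pearson
statistic with no correction. Continuous variables are routed by a
Shapiro-Wilk normality test (alpha = 0.05 in both groups) to either
mean +/- SD with Welch's t-test or median (P25, P75) with the
Mann-Whitney U-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "chisq_2x2_corrected",
    "chisq_rxc",
    "mann_whitney",
    "descriptive_table",
]


def chisq_2x2_corrected(a: int, b: int, c: int, d: int):
    """Yates-corrected 2x2 chi-square: N*(max(|ad-bc|-N/2, 0))^2/(R1*R2*C1*C2).

    Raises on a zero margin (where Fisher's exact test is the appropriate
    choice). Returns ``(chi2, p)``.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin; use Fisher's exact test instead")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def chisq_rxc(table):
    """Plain Pearson chi-square for an r x c table, df = (r-1)(c-1), no
    continuity correction. All-zero rows/columns are dropped with a warning.
    Returns ``(chi2, df, p)``."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0):
        raise ValueError("cell counts must be nonnegative")
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn(
            "dropping all-zero row(s)/column(s) from the contingency table",
            UserWarning,
            stacklevel=2,
        )
        t = t[keep_rows][:, keep_cols]
    if min(t.shape) < 2:
        raise ValueError("table degenerate after dropping zero margins")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).mean() > 0.2:
        warnings.warn(
            "sparse cells (>20% expected counts < 5); chi-square approximation "
            "may be poor",
            UserWarning,
            stacklevel=2,
        )
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def mann_whitney(x, y):
    """Mann-Whitney U with midrank ties.

    Exact p by enumeration for small samples without ties (both n <= 20),
    otherwise the continuity-corrected normal approximation. Returns
    ``(U, Z, p)`` where U counts pairs with x below y and Z is the
    tie-corrected normal deviate of U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    z = (u - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return u, float(z), float(res.pvalue)


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def descriptive_table(
    cohort: pd.DataFrame,
    group_col: str = "group",
    variables: list[str] | None = None,
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group characteristic table with automatic summary/test routing.

    Continuous variables: Shapiro-Wilk in both groups at ``shapiro_alpha``
    routes to mean +/- SD with Welch's t-test, otherwise to median (P25, P75)
    with the Mann-Whitney U-test. Binary 0/1 variables use the
    Yates-corrected 2x2 chi-square; other categoricals the plain Pearson
    chi-square. Constant variables are reported with zero spread and no test.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    labels = cohort[group_col].unique()
    if len(labels) != 2:
        raise ValueError("descriptive table compares exactly two groups")
    g0 = cohort[cohort[group_col] == labels[0]]
    g1 = cohort[cohort[group_col] == labels[1]]
    if variables is None:
        variables = [c for c in cohort.columns if c not in (group_col, "subject_id")]
    rows = []
    for var in variables:
        s0, s1 = g0[var].dropna(), g1[var].dropna()
        if pd.api.types.is_numeric_dtype(cohort[var]) and not _is_binary(cohort[var]):
            if s0.nunique() <= 1 and s1.nunique() <= 1:
                rows.append(
                    dict(variable=var, summary_type="constant",
                         group_a=f"{s0.mean():.2f} +/- 0.00",
                         group_b=f"{s1.mean():.2f} +/- 0.00",
                         statistic=np.nan, p_value=np.nan, test="none")
                )
                continue
            normal = all(
                stats.shapiro(s)[1] > shapiro_alpha
                for s in (s0, s1)
                if s.nunique() > 1 and len(s) >= 3
            )
            if normal:
                t, p = stats.ttest_ind(s0, s1, equal_var=False)
                rows.append(
                    dict(variable=var, summary_type="mean_sd",
                         group_a=f"{s0.mean():.2f} +/- {s0.std():.2f}",
                         group_b=f"{s1.mean():.2f} +/- {s1.std():.2f}",
                         statistic=float(t), p_value=float(p), test="welch_t")
                )
            else:
                _, z, p = mann_whitney(s0, s1)
                rows.append(
                    dict(variable=var, summary_type="median_iqr",
                         group_a=f"{s0.median():.2f} ({s0.quantile(.25):.2f}, "
                                 f"{s0.quantile(.75):.2f})",
                         group_b=f"{s1.median():.2f} ({s1.quantile(.25):.2f}, "
                                 f"{s1.quantile(.75):.2f})",
                         statistic=z, p_value=p, test="mann_whitney")
                )
        else:
            tab = pd.crosstab(cohort[group_col], cohort[var])
            if tab.shape[1] < 2:
                rows.append(
                    dict(variable=var, summary_type="constant",
                         group_a=str(s0.iloc[0]) if len(s0) else "",
                         group_b=str(s1.iloc[0]) if len(s1) else "",
                         statistic=np.nan, p_value=np.nan, test="none")
                )
                continue
            arr = tab.to_numpy()
            if arr.shape == (2, 2):
                chi2, p = chisq_2x2_corrected(*arr.ravel())
                test = "chisq_yates"
            else:
                chi2, _, p = chisq_rxc(arr)
                test = "chisq_pearson"
            counts0 = ", ".join(f"{k}:{v}" for k, v in tab.loc[labels[0]].items())
            counts1 = ", ".join(f"{k}:{v}" for k, v in tab.loc[labels[1]].items())
            rows.append(
                dict(variable=var, summary_type="counts",
                     group_a=counts0, group_b=counts1,
                     statistic=chi2, p_value=p, test=test)
            )
    out = pd.DataFrame(rows)
    out.attrs["groups"] = {"group_a": labels[0], "group_b": labels[1]}
    return out
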