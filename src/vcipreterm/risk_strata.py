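"""Three-tier risk stratification and its statistical validation battery.

VCI subjects are partitioned by their Model-4 predicted probability into
low (< 0.1), moderate (0.1-0.3, boundaries inclusive) and high (> 0.3) risk
tiers. The battery validates the stratification: a one-sided
Cochran-Armitage trend test for monotonically increasing preterm rates,
Spearman rank correlation between predicted probability and outcome, an
overall 3x2 Pearson chi-square (df = 2, no continuity correction), a Fisher
exact comparison of the low-risk tier against the control arm, and
Clopper-Pearson exact 95% intervals per tier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TIER_NAMES",
    "StratificationReport",
    "assign_tier",
    "cochran_armitage_trend",
    "spearman_outcome_correlation",
    "fisher_exact_2x2",
    "clopper_pearson",
    "stratification_report",
]

TIER_NAMES = ("low", "moderate", "high")


def assign_tier(probability, low: float = 0.1, high: float = 0.3):
    """Map predicted probabilities to low / moderate / high tiers.

    Boundary policy: the thresholds themselves belong to the moderate tier
    (low is strictly < ``low``; high is strictly > ``high``).
    """
    if not low < high:
        raise ValueError("tier thresholds are inverted")
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(p < low, "low", np.where(p <= high, "moderate", "high"))
    return out if out.ndim else str(out)


def cochran_armitage_trend(events, totals, scores=(1, 2, 3)):
    """Cochran-Armitage test for a linear trend in proportions.

    ``events[i]`` of ``totals[i]`` subjects in ordered tier ``i`` experienced
    the outcome; tiers are scored 1, 2, 3 by default. Returns
    ``(chi2, z, one_sided_p)`` where the one-sided p is in the direction of
    increasing risk with tier.
    """
    e = np.asarray(events, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    if e.shape != n.shape or e.shape != s.shape:
        raise ValueError("events, totals and scores must align")
    if np.any(n <= 0):
        raise ValueError("every tier must contain subjects")
    N = n.sum()
    E = e.sum()
    if E == 0 or E == N:
        raise ValueError("trend test undefined with a zero outcome margin")
    pbar = E / N
    num = float((s * (e - n * pbar)).sum())
    var = pbar * (1 - pbar) * float((n * s**2).sum() - (n * s).sum() ** 2 / N)
    z = num / math.sqrt(var)
    return z * z, z, float(stats.norm.sf(z))


def spearman_outcome_correlation(probabilities, outcomes):
    """Spearman rank correlation (midranks for ties) between predicted
    probabilities and the observed binary outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(p) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, pval = stats.spearmanr(p, y)
    return float(rho), float(pval)


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Fisher exact test with the sample odds ratio and Woolf logit CI.

    Table layout: rows are groups, columns are (event, no event) --
    ``[[a, b], [c, d]]``. The two-sided p sums hypergeometric tables at most
    as probable as the observed one. The odds ratio is the unconditional
    cross-product ratio ad/bc; with a zero cell the raw OR is reported as
    0 or inf while the CI applies the Haldane-Anscombe 0.5 correction.
    Returns ``(odds_ratio, p, (ci_low, ci_high))``.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("Fisher test undefined with a zero margin")
    res = stats.fisher_exact(np.array([[a, b], [c, d]]))
    if b * c == 0:
        orr = math.inf if a * d > 0 else 0.0
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif a * d == 0:
        orr = 0.0
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        orr = (a * d) / (b * c)
        aa, bb, cc, dd = a, b, c, d
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log((aa * dd) / (bb * cc))
    z = stats.norm.ppf(0.975)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    return float(orr), float(res.pvalue), ci


def clopper_pearson(x: int, n: int, conf: float = 0.95):
    """Exact (beta-quantile) binomial confidence interval for x/n."""
    if not 0 <= x <= n or n < 1:
        raise ValueError("require 0 <= x <= n with n >= 1")
    lo, hi = proportion_confint(x, n, alpha=1 - conf, method="beta")
    return float(lo), float(hi)


@dataclass
class StratificationReport:
    tiers: pd.DataFrame
    trend_chi2: float | None
    trend_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    overall_chi2: float | None
    overall_df: int | None
    overall_p: float | None
    fisher_or: float | None
    fisher_p: float | None
    fisher_ci: tuple[float, float] | None
    empty_tiers: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tiers": self.tiers.to_dict(orient="records"),
            "trend_chi2": self.trend_chi2,
            "trend_p": self.trend_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "overall_chi2": self.overall_chi2,
            "overall_df": self.overall_df,
            "overall_p": self.overall_p,
            "fisher_or": self.fisher_or,
            "fisher_p": self.fisher_p,
            "fisher_ci": list(self.fisher_ci) if self.fisher_ci else None,
            "empty_tiers": self.empty_tiers,
        }


def stratification_report(
    probabilities,
    outcomes,
    control_outcomes,
    low: float = 0.1,
    high: float = 0.3,
) -> StratificationReport:
    """Assemble the tier table and the full validation battery.

    ``probabilities``/``outcomes`` are the VCI subjects' Model-4 predictions
    and observed preterm flags; ``control_outcomes`` are the control arm's
    preterm flags for the low-risk-vs-control Fisher comparison. Tests whose
    requirements fail on degenerate inputs (e.g. empty tiers) are skipped and
    reported as None.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    ctrl = np.asarray(control_outcomes, dtype=int)
    tier = assign_tier(p, low=low, high=high)
    rows = []
    ranges = {"low": f"<{low}", "moderate": f"{low}-{high}", "high": f">{high}"}
    for name in TIER_NAMES:
        mask = tier == name
        n = int(mask.sum())
        ev = int(y[mask].sum())
        if n > 0:
            rate = ev / n
            ci = clopper_pearson(ev, n)
        else:
            rate, ci = float("nan"), (float("nan"), float("nan"))
        rows.append(
            dict(
                tier=name,
                probability_range=ranges[name],
                n=n,
                proportion=n / len(p) if len(p) else float("nan"),
                events=ev,
                event_rate=rate,
                ci_low=ci[0],
                ci_high=ci[1],
            )
        )
    tiers = pd.DataFrame(rows)
    empty = [r["tier"] for r in rows if r["n"] == 0]

    trend_chi2 = trend_p = None
    overall_chi2 = overall_p = None
    overall_df = None
    if not empty:
        try:
            trend_chi2, _, trend_p = cochran_armitage_trend(
                tiers["events"], tiers["n"]
            )
        except ValueError:
            pass
        table = np.column_stack(
            [tiers["events"], tiers["n"] - tiers["events"]]
        )
        if (table.sum(axis=0) > 0).all():
            chi2, pval, df, _ = stats.chi2_contingency(table, correction=False)
            overall_chi2, overall_p, overall_df = float(chi2), float(pval), int(df)
    else:
        warnings.warn(
            f"empty tier(s) {empty}; trend and overall tests skipped",
            UserWarning,
            stacklevel=2,
        )

    fisher_or = fisher_p = fisher_ci = None
    low_mask = tier == "low"
    if low_mask.any() and len(ctrl):
        a = int(y[low_mask].sum())
        b = int(low_mask.sum() - a)
        c = int(ctrl.sum())
        d = int(len(ctrl) - c)
        try:
            fisher_or, fisher_p, fisher_ci = fisher_exact_2x2(a, b, c, d)
        except ValueError:
            pass

    rho = rho_p = None
    try:
        rho, rho_p = spearman_outcome_correlation(p, y)
    except ValueError:
        pass

    return StratificationReport(
        tiers=tiers,
        trend_chi2=trend_chi2,
        trend_p=trend_p,
        spearman_rho=rho,
        spearman_p=rho_p,
        overall_chi2=overall_chi2,
        overall_df=overall_df,
        overall_p=overall_p,
        fisher_or=fisher_or,
        fisher_p=fisher_p,
        fisher_ci=fisher_ci,
        empty_tiers=empty,
    )
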