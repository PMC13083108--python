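"""Cumulative preterm-birth risk under censoring and competing risks.

Time scale is gestational age at delivery in days. Event codes follow the
competing-risk convention: 0 = censored, 1 = preterm birth (event of
interest), 2 = term delivery (competing event, which makes preterm birth
impossible). Kaplan-Meier incidence treats term delivery as censoring and
therefore overstates absolute risk when competing events exist; the
Aalen-Johansen cumulative incidence function (CIF) accounts for them and the
Gray test compares CIFs between groups.

The Gray test is implemented as the score test of the weighted (rho = 0)
log-rank statistic on the subdistribution risk set: subjects who experience
the competing event remain at risk thereafter, weighted by the ratio of
censoring-survival probabilities (Geskus reweighting). With no censoring the
weights are all one, and with no competing events the statistic reduces
exactly to the standard log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "CENSORED",
    "PRETERM_EVENT",
    "TERM_EVENT",
    "DEFAULT_LANDMARKS_DAYS",
    "events_from_cohort",
    "km_incidence",
    "logrank_test",
    "cox_hr",
    "cif_competing",
    "gray_test",
    "incidence_table",
]

CENSORED, PRETERM_EVENT, TERM_EVENT = 0, 1, 2

# 32 / 34 / 36 / 37 completed weeks in days
DEFAULT_LANDMARKS_DAYS = (224, 238, 252, 259)


def events_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject event records (time, code, group) from a cohort table.

    Every synthetic subject delivers, so code is 1 (preterm) or 2 (term);
    code 0 is retained in the schema for externally supplied censored data.
    """
    time = cohort["ga_delivery"].to_numpy(dtype=float)
    code = np.where(cohort["preterm"].to_numpy(dtype=int) == 1,
                    PRETERM_EVENT, TERM_EVENT)
    rec = pd.DataFrame(
        {"time": time, "code": code, "group": cohort["group"].to_numpy()}
    )
    if (rec["time"] < 196).any():
        raise ValueError("delivery before 196 days is outside the study window")
    return rec


@dataclass
class IncidenceCurve:
    """Step-function cumulative incidence with pointwise 95% CI."""

    times: np.ndarray
    incidence: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def at(self, t: float) -> float:
        """Right-continuous evaluation (events at ``t`` are included)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.incidence[idx]) if idx >= 0 else 0.0

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0, 0.0
        return float(self.ci_low[idx]), float(self.ci_high[idx])


def km_incidence(times, codes) -> IncidenceCurve:
    """1 - Kaplan-Meier estimate of preterm delivery (code 1 is the event;
    codes 0 and 2 are treated as censoring), with Greenwood CIs."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=(c == PRETERM_EVENT))
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    return IncidenceCurve(
        times=surv.index.to_numpy(dtype=float),
        incidence=1.0 - surv.to_numpy(dtype=float),
        ci_low=1.0 - ci.iloc[:, 1].to_numpy(dtype=float),
        ci_high=1.0 - ci.iloc[:, 0].to_numpy(dtype=float),
    )


def logrank_test(times, codes, groups):
    """Two-group log-rank test of the preterm-specific curves (term delivery
    censored). Returns ``(chi2, p)``."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank comparison needs exactly two groups")
    ev = c == PRETERM_EVENT
    if not ev.any():
        raise ValueError("log-rank test undefined with zero events")
    res = _ll_logrank(
        t[g == labels[0]], t[g == labels[1]],
        event_observed_A=ev[g == labels[0]],
        event_observed_B=ev[g == labels[1]],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_hr(times, codes, group_indicator):
    """Cox proportional-hazards HR for a binary group indicator.

    Partial likelihood with Breslow tie handling (many tied delivery days are
    expected on a day-resolution scale). Returns
    ``(hr, (ci_low, ci_high), p, flagged)`` where ``flagged`` marks a
    monotone-likelihood fit (all events in one group).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes, dtype=int)
    x = np.asarray(group_indicator, dtype=float)
    ev = (c == PRETERM_EVENT).astype(int)
    if ev.sum() < 2:
        raise ValueError("need at least 2 events for Cox regression")
    if np.ptp(x) == 0:
        raise ValueError("group indicator is constant")
    ev_groups = np.unique(x[ev == 1])
    if ev_groups.size < 2:  # monotone likelihood; report a sentinel
        return float("inf") if ev_groups[0] == 1 else 0.0, (np.nan, np.nan), np.nan, True
    model = PHReg(t, x[:, None], status=ev, ties="breslow")
    res = model.fit(disp=0)
    b = float(res.params[0])
    se = float(res.bse[0])
    z = stats.norm.ppf(0.975)
    return (
        float(np.exp(b)),
        (float(np.exp(b - z * se)), float(np.exp(b + z * se))),
        float(2 * stats.norm.sf(abs(b / se))),
        False,
    )


def _aalen_johansen(t, c):
    """Aalen-Johansen CIFs for causes 1 and 2 plus event-free survival.

    Returns (times, cif1, cif2, surv, var1) where ``var1`` is the
    Aalen-Johansen (Greenwood-type) variance of the cause-1 CIF.
    """
    all_times = np.unique(t)
    out_times, cif1, cif2, ss, var1 = [], [], [], [], []
    at_risk = len(t)
    surv = 1.0
    cur1 = cur2 = 0.0
    var1_terms = 0.0
    for ut in all_times:
        here = t == ut
        d1 = int((here & (c == PRETERM_EVENT)).sum())
        d2 = int((here & (c == TERM_EVENT)).sum())
        d = d1 + d2
        if d > 0 and at_risk > 0:
            cur1 += surv * d1 / at_risk
            cur2 += surv * d2 / at_risk
            # delta-method variance increment for CIF1 (counting-process
            # Greenwood-type form)
            var1_terms += (surv**2) * (d1 / at_risk) * (1 - d1 / at_risk) / at_risk
            surv *= 1 - d / at_risk
            out_times.append(ut)
            cif1.append(cur1)
            cif2.append(cur2)
            ss.append(surv)
            var1.append(var1_terms)
        # censorings at ut leave the risk set after the events at ut
        at_risk -= int(here.sum())
    return (
        np.array(out_times),
        np.array(cif1),
        np.array(cif2),
        np.array(ss),
        np.array(var1),
    )


def cif_competing(times, codes):
    """Aalen-Johansen cumulative incidence per cause with a Greenwood-type
    variance for the preterm CIF.

    Returns a DataFrame indexed by event time with columns ``cif_preterm``,
    ``cif_term``, ``surv``, ``ci_low``, ``ci_high``. At every jump time
    ``cif_preterm + cif_term + surv == 1`` exactly (up to float round-off).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes, dtype=int)
    if not np.isin(c, [CENSORED, PRETERM_EVENT, TERM_EVENT]).all():
        raise ValueError("event codes must be 0, 1 or 2")
    ut, cif1, cif2, surv, var1 = _aalen_johansen(t, c)
    z = stats.norm.ppf(0.975)
    se = np.sqrt(var1)
    return pd.DataFrame(
        {
            "cif_preterm": cif1,
            "cif_term": cif2,
            "surv": surv,
            "ci_low": np.clip(cif1 - z * se, 0.0, 1.0),
            "ci_high": np.clip(cif1 + z * se, 0.0, 1.0),
        },
        index=pd.Index(ut, name="time"),
    )


def _censoring_km(t, c):
    """KM of the censoring distribution G(t) (censoring as the 'event')."""
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=(c == CENSORED))
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    vals = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)

    def G(x):
        idx = np.searchsorted(times, x, side="right") - 1
        return float(vals[idx]) if idx >= 0 else 1.0

    return G


def gray_test(times, codes, groups):
    """Gray's two-sample test for the cause-1 (preterm) CIF, rho = 0.

    Computed as a weighted log-rank statistic on the subdistribution risk
    set: after a competing event at time ``s`` a subject stays at risk with
    weight ``G(t-)/G(s)`` (censoring-survival reweighting). Returns
    ``(chi2, p)``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(codes, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("Gray test needs exactly two groups")
    if not (c == PRETERM_EVENT).any():
        raise ValueError("Gray test undefined with zero cause-1 events")
    G = _censoring_km(t, c)
    g1 = g == labels[1]
    event_times = np.unique(t[c == PRETERM_EVENT])
    U = 0.0
    V = 0.0
    eps = 1e-9
    for ut in event_times:
        gt = G(ut - eps)
        # natural risk set: event-free and uncensored up to ut
        natural = t >= ut
        y1 = float(natural[g1].sum())
        y0 = float(natural[~g1].sum())
        # competing-event subjects remain with IPC weights
        comp = (c == TERM_EVENT) & (t < ut)
        if comp.any():
            w = gt / np.array([G(s) for s in t[comp]])
            y1 += float(w[g1[comp]].sum())
            y0 += float(w[~g1[comp]].sum())
        y = y1 + y0
        d1 = float(((t == ut) & (c == PRETERM_EVENT) & g1).sum())
        d = float(((t == ut) & (c == PRETERM_EVENT)).sum())
        if y <= 1 or d == 0:
            continue
        U += d1 - d * y1 / y
        V += d * (y1 / y) * (1 - y1 / y) * (y - d) / (y - 1)
    if V <= 0:
        raise ValueError("Gray test has zero variance on this data")
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def incidence_table(
    cohort: pd.DataFrame, landmarks=DEFAULT_LANDMARKS_DAYS
) -> pd.DataFrame:
    """Per-group landmark summary of cumulative preterm incidence.

    For each group and landmark day: number still at risk just before the
    landmark, preterm events in the window since the previous landmark, and
    the Kaplan-Meier cumulative incidence with its 95% CI at the landmark
    (right-continuous, so events on the landmark day are included).
    """
    rec = events_from_cohort(cohort)
    rows = []
    for label, sub in rec.groupby("group"):
        curve = km_incidence(sub["time"], sub["code"])
        prev = -np.inf
        for lm in landmarks:
            at_risk = int((sub["time"] >= lm).sum())
            events = int(
                (
                    (sub["time"] > prev)
                    & (sub["time"] <= lm)
                    & (sub["code"] == PRETERM_EVENT)
                ).sum()
            )
            lo, hi = curve.ci_at(lm)
            rows.append(
                dict(
                    group=label,
                    landmark_days=lm,
                    landmark_weeks=lm / 7.0,
                    at_risk=at_risk,
                    events=events,
                    cumulative_incidence=curve.at(lm),
                    ci_low=lo,
                    ci_high=hi,
                )
            )
            prev = lm
    return pd.DataFrame(rows)
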