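"""Discrimination, calibration and bootstrap internal validation.

AUC is the Mann-Whitney concordance probability (ties counted 1/2); the
operating point is chosen by the Youden index over observed thresholds;
calibration uses the Hosmer-Lemeshow deciles-of-risk test (g = 10); and
internal validation resamples subjects with replacement, refitting the full
model-construction pipeline in every resample and summarising the resample
AUCs by their mean and 2.5/97.5 percentile interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .model_build import build_model, prepare_design

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "youden_cutoff",
    "hosmer_lemeshow",
    "bootstrap_validate",
    "evaluate_model",
]


@dataclass
class EvaluationReport:
    model_id: int | None
    auc: float
    auc_ci: tuple[float, float]
    bootstrap_auc_mean: float
    bootstrap_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    n_events: int
    n_total: int
    bootstrap_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "bootstrap_auc_mean": self.bootstrap_auc_mean,
            "bootstrap_ci": list(self.bootstrap_ci),
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "hl_chi2": self.hl_chi2,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "n_events": self.n_events,
            "n_total": self.n_total,
        }


def roc_auc(probabilities, labels):
    """AUC with empirical ROC points.

    Computed as the normalised Mann-Whitney U statistic (ties 1/2), which is
    identical to the trapezoidal area under the empirical ROC curve.
    Returns ``(auc, fpr, tpr, thresholds)``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined with a single outcome class")
    ranks = stats.rankdata(p)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thresholds = roc_curve(y, p)
    return float(auc), fpr, tpr, thresholds


def _auc_only(p, y):
    n1 = y.sum()
    n0 = len(y) - n1
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _hanley_mcneil_ci(auc, n1, n0, conf=0.95):
    """Hanley-McNeil standard-error approximation for the AUC CI."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    z = stats.norm.ppf(0.5 + conf / 2)
    half = z * np.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def youden_cutoff(probabilities, labels):
    """Operating point maximising sensitivity + specificity - 1.

    The scan runs over the observed scores as candidate cutoffs (classify
    positive when score >= cutoff); exact ties in J are broken toward the
    lowest cutoff, favouring sensitivity. Returns
    ``(cutoff, sensitivity, specificity, accuracy)``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate ROC: a single outcome class")
    cand = np.unique(p)
    best = None
    for c in cand:  # ascending, so strict improvement keeps the lowest tie
        pos = p >= c
        tp = int((pos & (y == 1)).sum())
        tn = int((~pos & (y == 0)).sum())
        sens = tp / n1
        spec = tn / n0
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec, (tp + tn) / len(y))
    _, cutoff, sens, spec, acc = best
    return float(cutoff), float(sens), float(spec), float(acc)


def hosmer_lemeshow(probabilities, labels, groups: int = 10):
    """Hosmer-Lemeshow goodness-of-fit chi-square over deciles of risk.

    Subjects are grouped by quantile ranks of predicted probability with
    ties kept in one group; the statistic sums
    (O_g - E_g)^2 / (n_g * pbar_g * (1 - pbar_g)) over groups, equivalent to
    the (O-E)^2/E sum over both outcome classes. ``df = groups - 2``. Groups
    with zero expected spread are merged with their neighbour.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) < 2 * groups:
        raise ValueError("need n >= 2*groups for the Hosmer-Lemeshow test")
    order = pd.Series(p).rank(method="average")
    try:
        bins = pd.qcut(order, groups, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(p), dtype=int)
    frame = pd.DataFrame({"p": p, "y": y, "g": bins})
    agg = frame.groupby("g").agg(n=("y", "size"), o=("y", "sum"), e=("p", "sum"))
    # merge groups whose expected counts are degenerate (pbar 0 or 1)
    merged = []
    pending = None
    for _, row in agg.iterrows():
        if pending is not None:
            row = row + pending
            pending = None
        pbar = row["e"] / row["n"]
        if pbar <= 0 or pbar >= 1:
            pending = row
        else:
            merged.append(row)
    if pending is not None and merged:
        merged[-1] = merged[-1] + pending
    table = pd.DataFrame(merged)
    g_eff = len(table)
    if g_eff < 2:
        raise ValueError("too few usable risk groups for the test")
    pbar = table["e"] / table["n"]
    chi2 = float(
        (((table["o"] - table["e"]) ** 2) / (table["n"] * pbar * (1 - pbar))).sum()
    )
    df = max(g_eff - 2, 0)
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else float("nan")
    return chi2, int(df), p


def bootstrap_validate(
    data: pd.DataFrame,
    model_id: int,
    B: int = 1000,
    seed: int = 0,
    refit: bool = True,
    optimism: bool = False,
):
    """Bootstrap internal validation of one model's AUC.

    Subjects are resampled with replacement ``B`` times; the full
    construction pipeline (screen -> LASSO -> fit, or the direct prespecified
    fit) is re-run on each resample and the resample-apparent AUC recorded.
    Returns ``(mean, (lo, hi), n_redraws)`` with the percentile 95% interval.
    With ``optimism=True`` the Harrell optimism-corrected AUC is returned as
    the mean instead: apparent - mean(auc_boot - auc_boot_on_original).
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100")
    rng = np.random.default_rng(seed)
    data = data.reset_index(drop=True)
    n = len(data)
    y_orig = data["preterm"].to_numpy(dtype=int)
    aucs = np.empty(B)
    optimisms = np.empty(B)
    redraws = 0
    if optimism:
        apparent_model = build_model(model_id, data, seed=seed)
        X_orig, _ = prepare_design(data, model_id)
        apparent = _auc_only(apparent_model.predicted, y_orig)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y_orig[idx]
            if 0 < yb.sum() < n:
                break
            redraws += 1
        sample = data.iloc[idx]
        if refit:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_model(model_id, sample, seed=seed)
            aucs[b] = _auc_only(model.predicted, yb)
            if optimism:
                Xo = X_orig[model.variables] if set(model.variables) <= set(
                    X_orig.columns
                ) else prepare_design(data, model_id)[0][model.variables]
                test_auc = _auc_only(model.predict(Xo), y_orig)
                optimisms[b] = aucs[b] - test_auc
        else:
            probs = data["predicted"].to_numpy(dtype=float)[idx]
            aucs[b] = _auc_only(probs, yb)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    if optimism:
        return float(apparent - optimisms.mean()), (float(lo), float(hi)), redraws
    return float(aucs.mean()), (float(lo), float(hi)), redraws


def evaluate_model(
    data: pd.DataFrame,
    model_id: int,
    B: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Fit one model and assemble its full evaluation report."""
    model = build_model(model_id, data, seed=seed)
    y = data["preterm"].to_numpy(dtype=int)
    auc, *_ = roc_auc(model.predicted, y)
    cutoff, sens, spec, acc = youden_cutoff(model.predicted, y)
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(model.predicted, y)
    boot_mean, boot_ci, redraws = bootstrap_validate(
        data, model_id, B=B, seed=seed
    )
    return EvaluationReport(
        model_id=model_id,
        auc=auc,
        auc_ci=_hanley_mcneil_ci(auc, int(y.sum()), int(len(y) - y.sum())),
        bootstrap_auc_mean=boot_mean,
        bootstrap_ci=boot_ci,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        hl_chi2=hl_chi2,
        hl_df=hl_df,
        hl_p=hl_p,
        n_events=int(y.sum()),
        n_total=int(len(y)),
        bootstrap_redraws=redraws,
    )
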