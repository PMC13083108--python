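"""Construction of the four preterm-birth prediction models.

Models 1-3 follow a three-step pipeline on the VCI arm: univariate logistic
screening at P <= 0.10, LASSO variable selection with a cross-validated
penalty, and a final maximum-likelihood multivariable logistic fit. Model 4
is prespecified -- maternal age, vasa previa, the head-to-femur discordance
index (BPD_FL_diff) and the composite Doppler deviation (Z_doppler) enter
directly with no screening or shrinkage, keeping the model estimable from
midtrimester data alone and avoiding the PI/RI collinearity by construction.

Variable pools:

* Model 1 (midtrimester baseline): maternal age, advanced-age flag (>= 35 y),
  comorbidity count, mid BPD, FL, RI.
* Model 2 (predelivery benchmark): late BPD, FL, AC, S/D and EFW.
* Model 3 (mid + late combined): all static mid and late ultrasound
  parameters plus the standardized BPD growth-rate quartiles (Q2-Q4 vs Q1).
* Model 4 (prespecified): maternal age, vasa previa, BPD_FL_diff, Z_doppler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numba import njit
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ModelSpec",
    "FittedModel",
    "MODEL_SPECS",
    "MissingStageError",
    "SeparationWarning",
    "ADVANCED_AGE_YEARS",
    "univariate_screen",
    "lasso_select",
    "lasso_path_selection",
    "fit_logistic",
    "build_model",
    "prepare_design",
]

ADVANCED_AGE_YEARS = 35.0


class MissingStageError(ValueError):
    """A model was requested on a cohort lacking its required visit data."""


class SeparationWarning(UserWarning):
    """(Quasi-)complete separation encountered in a logistic fit."""


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    candidates: tuple[str, ...]
    categorical: tuple[str, ...] = ()
    screen: bool = True
    lasso: bool = True
    screening_alpha: float = 0.10
    requires_late: bool = False


_MID_STATIC = (
    "bpd_mid",
    "fl_mid",
    "ac_mid",
    "hc_mid",
    "pi_mid",
    "ri_mid",
    "sd_ratio_mid",
    "afd_mid",
)
_LATE_STATIC = ("bpd_late", "fl_late", "ac_late", "sd_ratio_late", "efw")

MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(
        1,
        candidates=(
            "maternal_age",
            "advanced_age",
            "comorbidity_count",
            "bpd_mid",
            "fl_mid",
            "ri_mid",
        ),
    ),
    2: ModelSpec(2, candidates=_LATE_STATIC, requires_late=True),
    3: ModelSpec(
        3,
        candidates=_MID_STATIC + _LATE_STATIC,
        categorical=("d_bpd_quartile",),
        requires_late=True,
    ),
    4: ModelSpec(
        4,
        candidates=("maternal_age", "vasa_previa", "bpd_fl_diff", "z_doppler"),
        screen=False,
        lasso=False,
    ),
}


@dataclass
class FittedModel:
    """A fitted logistic model with its odds-ratio table and predictions."""

    model_id: int | None
    variables: list[str]
    intercept: float
    coefficients: dict[str, float]
    or_table: pd.DataFrame
    predicted: np.ndarray
    n_events: int
    n_total: int
    converged: bool = True
    separation_flagged: bool = False
    screen_table: pd.DataFrame | None = None
    lasso_selected: list[str] | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.intercept + sum(
            self.coefficients[v] * X[v].to_numpy(dtype=float) for v in self.variables
        )
        return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "variables": self.variables,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "or_table": self.or_table.to_dict(orient="records"),
            "n_events": int(self.n_events),
            "n_total": int(self.n_total),
            "separation_flagged": self.separation_flagged,
        }


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 60,
                     tol: float = 1e-10):
    """Small dense Newton-Raphson logistic MLE; returns (beta, cov, converged).

    Used for the many single-predictor screening fits where per-call overhead
    dominates; the multivariable fits go through statsmodels.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(grad).max() < tol:
            converged = True
            break
        if np.abs(beta).max() > 50:  # separation guard
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def _dummy_columns(frame: pd.DataFrame, col: str) -> pd.DataFrame:
    """Quartile dummies Q2/Q3/Q4 vs reference Q1 for a categorical column."""
    levels = ["Q2", "Q3", "Q4"]
    out = pd.DataFrame(index=frame.index)
    for lev in levels:
        out[f"{col}_{lev}"] = (frame[col] == lev).astype(float)
    return out


def univariate_screen(
    data: pd.DataFrame,
    outcome: str = "preterm",
    candidates: Sequence[str] = (),
    categorical: Sequence[str] = (),
    alpha: float = 0.10,
) -> pd.DataFrame:
    """One single-predictor logistic fit per candidate; retain at Wald P <= alpha.

    Categorical candidates enter as Q2/Q3/Q4-vs-Q1 dummies fitted jointly;
    the candidate is retained when any dummy reaches the threshold. Complete
    separation is flagged with an infinite-OR sentinel instead of crashing.
    """
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; screening is undefined")
    rows = []
    for cand in list(candidates) + list(categorical):
        if cand in categorical:
            dummies = _dummy_columns(data, cand)
            X = np.column_stack([np.ones(len(data)), dummies.to_numpy()])
            names = list(dummies.columns)
        else:
            x = data[cand].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                rows.append(
                    dict(variable=cand, term=cand, beta=np.nan, wald_z=np.nan,
                         odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                         p_value=np.nan, retained=False, flagged=True)
                )
                continue
            X = np.column_stack([np.ones(len(data)), x])
            names = [cand]
        beta, cov, converged = _newton_logistic(X, y)
        for j, name in enumerate(names, start=1):
            b = beta[j]
            se = np.sqrt(cov[j, j]) if np.isfinite(cov[j, j]) else np.nan
            separated = (not converged) and abs(b) > 10
            if separated or not np.isfinite(se) or se <= 0:
                z = np.nan
                p = np.nan
                orr = np.inf if b > 0 else 0.0
                lo = hi = np.nan
                flagged = True
            else:
                z = b / se
                p = 2 * stats.norm.sf(abs(z))
                orr = np.exp(b)
                lo, hi = np.exp(b - 1.959963984540054 * se), np.exp(
                    b + 1.959963984540054 * se
                )
                flagged = False
            rows.append(
                dict(variable=cand, term=name, beta=b, wald_z=z, odds_ratio=orr,
                     ci_low=lo, ci_high=hi, p_value=p, retained=False,
                     flagged=flagged)
            )
    table = pd.DataFrame(rows)
    # retain a variable when any of its terms reaches the threshold
    keep = (
        table.groupby("variable", sort=False)["p_value"]
        .min()
        .le(alpha)
        .fillna(False)
    )
    table["retained"] = table["variable"].map(keep)
    return table


def _cv_grid() -> np.ndarray:
    # inverse-penalty grid for the L1 path (small C = heavy shrinkage); the
    # upper end is effectively unpenalised for standardised predictors
    return np.logspace(-2.5, 2.0, 10)


@njit(cache=True)
def _l1_cd_kernel(X1, y, lam, beta, outer, tol):  # pragma: no cover - jitted
    n, p = X1.shape
    for _ in range(outer):
        eta = X1 @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        for i in range(n):
            if w[i] < 1e-6:
                w[i] = 1e-6
        r = y - mu  # w * (z - eta) with working response z
        wx2 = np.zeros(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X1[i, j] * X1[i, j]
            wx2[j] = s
        beta_prev = beta.copy()
        for _ in range(30):
            delta_max = 0.0
            for j in range(p):
                bj = beta[j]
                rho = wx2[j] * bj
                for i in range(n):
                    rho += X1[i, j] * r[i]
                if j == 0:
                    new = rho / wx2[j]
                else:
                    a = abs(rho) - lam
                    new = (a / wx2[j]) * np.sign(rho) if a > 0.0 else 0.0
                d = new - bj
                if d != 0.0:
                    for i in range(n):
                        r[i] -= d * w[i] * X1[i, j]
                    beta[j] = new
                    if abs(d) > delta_max:
                        delta_max = abs(d)
            if delta_max < tol:
                break
        bmax = 0.0
        dmax = 0.0
        for j in range(p):
            if abs(beta[j]) > bmax:
                bmax = abs(beta[j])
            if abs(beta[j] - beta_prev[j]) > dmax:
                dmax = abs(beta[j] - beta_prev[j])
        if bmax > 30.0:  # separation guard at tiny penalties
            break
        if dmax < 10.0 * tol:
            break
    return beta


def _l1_logistic(X1, y, lam, beta=None, outer=40, tol=1e-7):
    """L1-penalised logistic regression by proximal-Newton coordinate descent
    (IRLS working response + soft thresholding, glmnet-style).

    ``X1`` carries the intercept in column 0, which is never penalised.
    Objective: sum_i log(1+exp(-eta_i)) + lam * sum_{j>=1} |beta_j|,
    i.e. lam corresponds to 1/C in the liblinear parameterisation (except
    that the intercept is not penalised here).
    """
    X1 = np.ascontiguousarray(X1, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if beta is None:
        beta = np.zeros(X1.shape[1])
    else:
        beta = np.asarray(beta, dtype=np.float64).copy()
    return _l1_cd_kernel(X1, y, float(lam), beta, int(outer), float(tol))


def _l1_path(X1, y, Cs):
    """Warm-started coefficient path over ascending C (descending penalty)."""
    betas = []
    beta = None
    for k, c in enumerate(Cs):
        beta = _l1_logistic(X1, y, lam=1.0 / c, beta=beta)
        betas.append(beta.copy())
        if np.abs(beta).max() > 30:
            # separation regime: smaller penalties only inflate further
            betas.extend(beta.copy() for _ in Cs[k + 1 :])
            break
    return betas


def lasso_select(
    X: pd.DataFrame,
    y: Sequence[int],
    seed: int = 0,
    n_folds: int = 10,
    Cs: np.ndarray | None = None,
) -> list[str]:
    """L1-penalised logistic selection with the penalty chosen by
    cross-validated deviance (minimum rule, seeded fold assignment).

    Predictors are standardised internally; selection is the set of non-zero
    coefficients at the chosen penalty (empty set returned with a warning
    when everything shrinks away).
    """
    if X.shape[1] < 2:
        raise ValueError("LASSO selection needs at least 2 candidates")
    y = np.asarray(y, dtype=int)
    Xs = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    Xa = Xs.to_numpy(dtype=float)
    if Cs is None:
        Cs = _cv_grid()
    n_folds = min(n_folds, int(np.bincount(y).min()))
    n_folds = max(n_folds, 2)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    Cs = np.sort(np.asarray(Cs, dtype=float))
    X1 = np.column_stack([np.ones(len(Xa)), Xa])
    deviance = np.zeros(len(Cs))
    for train, test in cv.split(Xa, y):
        betas = _l1_path(X1[train], y[train].astype(float), Cs)
        for k, beta in enumerate(betas):
            p = 1.0 / (1.0 + np.exp(-(X1[test] @ beta)))
            p = p.clip(1e-12, 1 - 1e-12)
            deviance[k] += -2 * np.sum(
                y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)
            )
    best = Cs[int(np.argmin(deviance))]
    beta = _l1_logistic(X1, y.astype(float), lam=1.0 / best)
    selected = [name for name, b in zip(X.columns, beta[1:]) if b != 0.0]
    if not selected:
        warnings.warn(
            "LASSO shrank every coefficient to zero at the chosen penalty",
            UserWarning,
            stacklevel=2,
        )
    return selected


def lasso_path_selection(
    X: pd.DataFrame, y: Sequence[int], Cs: np.ndarray | None = None
) -> list[tuple[float, frozenset[str]]]:
    """Selected-variable sets along the L1 path (ascending C, i.e. decreasing
    penalty); used to inspect path behaviour."""
    y = np.asarray(y, dtype=int)
    Xs = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    Xa = Xs.to_numpy(dtype=float)
    if Cs is None:
        Cs = _cv_grid()
    Cs = np.sort(np.asarray(Cs, dtype=float))
    X1 = np.column_stack([np.ones(len(Xa)), Xa])
    betas = _l1_path(X1, np.asarray(y, dtype=float), Cs)
    return [
        (float(c), frozenset(n for n, b in zip(X.columns, beta[1:]) if b != 0.0))
        for c, beta in zip(Cs, betas)
    ]


def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 0.1):
    """Lightly L2-penalised Newton logistic fit (separation fallback).

    Predictors are standardised internally; the penalty (excluding the
    intercept) keeps the optimum finite under quasi-complete separation.
    Returns the raw-scale coefficient vector (intercept first) and the
    fitted probabilities.
    """
    mu_x = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(len(X)), (X - mu_x) / sd])
    p = Xs.shape[1]
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    for _ in range(100):
        eta = Xs @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xs.T @ (y - mu) - pen @ beta
        hess = (Xs * w[:, None]).T @ Xs + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    predicted = 1.0 / (1.0 + np.exp(-(Xs @ beta)))
    coefs = np.empty(p)
    coefs[1:] = beta[1:] / sd
    coefs[0] = beta[0] - float((beta[1:] * mu_x / sd).sum())
    return coefs, predicted


def _check_design(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [np.ones(len(X))]
        for name in X.columns:
            trial = np.column_stack(cols + [X[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(name)
            else:
                cols.append(X[name].to_numpy(dtype=float))
        raise ValueError(f"singular design; collinear column(s): {bad}")


def fit_logistic(
    X: pd.DataFrame, y: Sequence[int], model_id: int | None = None
) -> FittedModel:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    On (quasi-)complete separation the fit falls back to a lightly ridge-
    penalised estimate and the result is flagged; a singular design raises a
    ``ValueError`` naming the collinear columns.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > number of predictors")
    _check_design(X)
    exog = sm.add_constant(X.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y, exog).fit(disp=0, method="newton", tol=1e-10,
                                        maxiter=60)
            bse_arr = np.asarray(res.bse, dtype=float)
            if not res.mle_retvals["converged"] or not np.all(
                np.isfinite(bse_arr)
            ):
                raise RuntimeError("suspected separation")
        except Exception:
            separation = True
    if separation:
        warnings.warn(
            "separation detected; reporting a ridge-penalised fallback fit",
            SeparationWarning,
            stacklevel=2,
        )
        coefs, predicted = _ridge_logistic(X.to_numpy(dtype=float), y)
        params = pd.Series(coefs, index=exog.columns)
        bse = pd.Series(np.nan, index=exog.columns)
    else:
        params = pd.Series(res.params, index=exog.columns)
        bse = pd.Series(res.bse, index=exog.columns)
        predicted = np.asarray(res.predict(exog), dtype=float)
    zcrit = stats.norm.ppf(0.975)
    variables = list(X.columns)
    rows = []
    for name in variables:
        b, se = params[name], bse[name]
        ok = np.isfinite(se) and se > 0
        rows.append(
            dict(
                variable=name,
                beta=float(b),
                se=float(se),
                wald_z=float(b / se) if ok else np.nan,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - zcrit * se)) if ok else np.nan,
                ci_high=float(np.exp(b + zcrit * se)) if ok else np.nan,
                p_value=float(2 * stats.norm.sf(abs(b / se))) if ok else np.nan,
            )
        )
    return FittedModel(
        model_id=model_id,
        variables=variables,
        intercept=float(params["const"]),
        coefficients={v: float(params[v]) for v in variables},
        or_table=pd.DataFrame(rows),
        predicted=predicted,
        n_events=int(y.sum()),
        n_total=int(len(y)),
        converged=not separation,
        separation_flagged=separation,
    )


def prepare_design(data: pd.DataFrame, model_id: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the candidate design matrix and outcome for one model.

    Derives ``advanced_age`` (>= 35 years) and ``comorbidity_count`` when
    needed, and expands categorical candidates into dummies. Raises
    :class:`MissingStageError` when late-visit columns are required but absent.
    """
    spec = MODEL_SPECS[model_id]
    frame = data.copy()
    if "advanced_age" in spec.candidates and "advanced_age" not in frame:
        frame["advanced_age"] = (frame["maternal_age"] >= ADVANCED_AGE_YEARS).astype(
            float
        )
    if "comorbidity_count" in spec.candidates and "comorbidity_count" not in frame:
        flags = [c for c in ("hypertension", "gdm", "hypothyroidism") if c in frame]
        frame["comorbidity_count"] = frame[flags].sum(axis=1).astype(float)
    needed = list(spec.candidates) + list(spec.categorical)
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        if spec.requires_late:
            raise MissingStageError(
                f"model {model_id} needs late-visit data; missing column(s): "
                f"{missing}"
            )
        raise MissingStageError(
            f"model {model_id} is missing required column(s): {missing}"
        )
    X = frame[list(spec.candidates)].astype(float)
    for cat in spec.categorical:
        X = pd.concat([X, _dummy_columns(frame, cat)], axis=1)
    y = frame["preterm"].to_numpy(dtype=int)
    return X, y


def build_model(model_id: int, data: pd.DataFrame, seed: int = 0) -> FittedModel:
    """Run the full construction pipeline for one model on a scored cohort.

    Models 1-3: univariate screen (P <= 0.10) -> LASSO selection -> final
    multivariable logistic fit. Model 4: direct prespecified fit. When
    screening or LASSO leaves fewer than one (respectively zero) variables,
    the pipeline falls back to the best-screening candidate so a model is
    always produced (relevant for bootstrap refits on resampled data).
    """
    spec = MODEL_SPECS[model_id]
    data = data.reset_index(drop=True)
    X_all, y = prepare_design(data, model_id)

    screen_table = None
    lasso_selected = None
    if spec.screen:
        screen_frame = pd.concat(
            [X_all, pd.Series(y, name="preterm", index=X_all.index)], axis=1
        )
        for cat in spec.categorical:
            screen_frame[cat] = data[cat].to_numpy()
        screen_table = univariate_screen(
            screen_frame,
            outcome="preterm",
            candidates=list(spec.candidates),
            categorical=list(spec.categorical),
            alpha=spec.screening_alpha,
        )
        retained_vars = [
            v
            for v in list(spec.candidates) + list(spec.categorical)
            if bool(screen_table.loc[screen_table.variable == v, "retained"].iloc[0])
        ]
        if not retained_vars:
            best = (
                screen_table.dropna(subset=["p_value"])
                .sort_values("p_value")
                .variable.iloc[0]
            )
            retained_vars = [best]
        cols = []
        for v in retained_vars:
            if v in spec.categorical:
                cols.extend(f"{v}_{q}" for q in ("Q2", "Q3", "Q4"))
            else:
                cols.append(v)
        X = X_all[cols]
    else:
        X = X_all

    if spec.lasso and X.shape[1] >= 2:
        lasso_selected = lasso_select(X, y, seed=seed)
        if lasso_selected:
            X = X[lasso_selected]

    fitted = fit_logistic(X, y, model_id=model_id)
    fitted.screen_table = screen_table
    fitted.lasso_selected = lasso_selected
    return fitted
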