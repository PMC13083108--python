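"""Population reference curves and growth-deviation metrics.

Reference curves are quadratic polynomials in exact gestational age (days)
fitted by ordinary least squares to the control arm, with a single
homoscedastic residual SD per parameter. Deviation metrics:

* ``Z = (observed - predicted at same GA) / residual SD``
* ``Z_doppler = sqrt((PI_z^2 + RI_z^2) / 2)`` -- nonnegative, directionless
  magnitude of umbilical-artery Doppler deviation; PI and RI are strongly
  collinear (r > 0.7), so their deviations are combined rather than entered
  separately.
* ``BPD_FL_diff = BPD_z - FL_z`` -- head-to-femur discordance capturing the
  brain-sparing asymmetric growth pattern of placental insufficiency.

Dynamic (two-visit) indicators follow the convention
``(late value - early value) / interval in weeks`` with biometric rates
reported in mm/week, plus the reference-anchored ``dRI = 0.55 - late RI`` and
``dPI = 0.78 - late PI``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceCurve",
    "DeviationScores",
    "DynamicIndicators",
    "DomainWarning",
    "DegenerateCurveError",
    "InsufficientDataError",
    "fit_reference_curve",
    "fit_reference_curves",
    "z_score",
    "z_doppler",
    "bpd_fl_diff",
    "dynamic_indicators",
    "quartile_bin",
    "score_cohort",
    "curves_to_json",
    "curves_from_json",
    "DEFAULT_GA_DOMAIN",
    "RI_REFERENCE",
    "PI_REFERENCE",
]

DEFAULT_GA_DOMAIN = (130, 200)

# Late-gestation umbilical-artery reference constants anchoring the
# single-visit dynamic indicators dRI and dPI.
RI_REFERENCE = 0.55
PI_REFERENCE = 0.78


class DomainWarning(UserWarning):
    """A gestational age falls outside the reference-curve domain."""


class DegenerateCurveError(ValueError):
    """The reference curve has zero residual SD; Z-scores are undefined."""


class InsufficientDataError(ValueError):
    """Too few points to fit a quadratic with a residual degree of freedom."""


@dataclass(frozen=True)
class ReferenceCurve:
    """Quadratic reference: predicted = a0 + a1*GA + a2*GA^2, GA in days."""

    parameter_name: str
    a0: float
    a1: float
    a2: float
    residual_sd: float
    ga_domain: tuple[float, float]
    n_fit: int

    def predict(self, ga_days):
        ga = np.asarray(ga_days, dtype=float)
        return self.a0 + self.a1 * ga + self.a2 * ga * ga


@dataclass(frozen=True)
class DeviationScores:
    bpd_z: float
    fl_z: float
    pi_z: float
    ri_z: float
    z_doppler: float
    bpd_fl_diff: float


@dataclass(frozen=True)
class DynamicIndicators:
    """Two-visit change indicators; biometric rates in mm/week."""

    d_bpd_std: float
    d_fl_std: float
    d_sd: float
    d_ri: float | None = None
    d_pi: float | None = None
    d_afd: float | None = None


def fit_reference_curve(
    ga_days: Sequence[float],
    values: Sequence[float],
    parameter_name: str,
    ga_domain: tuple[float, float] = DEFAULT_GA_DOMAIN,
) -> ReferenceCurve:
    """OLS quadratic fit of ``values`` on gestational age.

    Points outside ``ga_domain`` are dropped with a :class:`DomainWarning`.
    The residual SD uses ``df = n - 3``. Raises
    :class:`InsufficientDataError` for fewer than 4 usable points and
    ``ValueError`` for a rank-deficient design (e.g. all GA identical).
    """
    ga = np.asarray(ga_days, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ga.shape != vals.shape:
        raise ValueError("ga_days and values must have the same length")
    if not np.all(np.isfinite(ga)) or not np.all(np.isfinite(vals)):
        raise ValueError("non-finite input to reference-curve fit")
    lo, hi = ga_domain
    if not lo < hi:
        raise ValueError("ga_domain is inverted")
    inside = (ga >= lo) & (ga <= hi)
    if not inside.all():
        warnings.warn(
            f"{(~inside).sum()} point(s) outside GA domain [{lo}, {hi}] "
            f"dropped from {parameter_name!r} fit",
            DomainWarning,
            stacklevel=2,
        )
        ga, vals = ga[inside], vals[inside]
    n = ga.size
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 in-domain points to fit {parameter_name!r}, got {n}"
        )
    design = np.vander(ga, 3, increasing=True)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            f"rank-deficient design for {parameter_name!r} (degenerate GA values)"
        )
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    resid = vals - design @ coef
    residual_sd = float(np.sqrt((resid @ resid) / (n - 3)))
    return ReferenceCurve(
        parameter_name=parameter_name,
        a0=float(coef[0]),
        a1=float(coef[1]),
        a2=float(coef[2]),
        residual_sd=residual_sd,
        ga_domain=(float(lo), float(hi)),
        n_fit=int(n),
    )


def z_score(curve: ReferenceCurve, ga_days, observed, strict: bool = False):
    """Gestational-age-standardised deviation from the reference curve.

    Outside the curve domain the quadratic is extrapolated with a
    :class:`DomainWarning` by default; ``strict=True`` rejects instead.
    """
    if curve.residual_sd <= 0:
        raise DegenerateCurveError(
            f"reference curve {curve.parameter_name!r} has zero residual SD"
        )
    ga = np.asarray(ga_days, dtype=float)
    lo, hi = curve.ga_domain
    outside = (ga < lo) | (ga > hi)
    if np.any(outside):
        if strict:
            raise ValueError(
                f"GA outside reference domain [{lo}, {hi}] for "
                f"{curve.parameter_name!r}"
            )
        warnings.warn(
            f"extrapolating {curve.parameter_name!r} curve outside "
            f"domain [{lo}, {hi}]",
            DomainWarning,
            stacklevel=2,
        )
    z = (np.asarray(observed, dtype=float) - curve.predict(ga)) / curve.residual_sd
    return z if z.ndim else float(z)


def z_doppler(pi_z, ri_z):
    """Composite Doppler deviation magnitude sqrt((PI_z^2 + RI_z^2)/2)."""
    pi_z = np.asarray(pi_z, dtype=float)
    ri_z = np.asarray(ri_z, dtype=float)
    out = np.sqrt((pi_z**2 + ri_z**2) / 2.0)
    return out if out.ndim else float(out)


def bpd_fl_diff(bpd_z, fl_z):
    """Head-to-femur discordance BPD_z - FL_z."""
    out = np.asarray(bpd_z, dtype=float) - np.asarray(fl_z, dtype=float)
    return out if out.ndim else float(out)


def dynamic_indicators(
    mid_visit: Mapping[str, float], late_visit: Mapping[str, float]
) -> DynamicIndicators:
    """Two-visit change indicators from mid- and late-visit measurement dicts.

    Expects GA keys ``ga`` (days) and measurement keys ``bpd``/``fl``/``sd_ratio``
    (and optionally ``ri``, ``pi``, ``afd``) in each visit dict; biometrics in
    cm. Raises ``ValueError`` when the examination interval is not positive.
    """
    interval_weeks = (float(late_visit["ga"]) - float(mid_visit["ga"])) / 7.0
    if interval_weeks <= 0:
        raise ValueError("examination interval must be positive")

    def rate_mm(key):
        return (float(late_visit[key]) - float(mid_visit[key])) * 10.0 / interval_weeks

    d_afd = rate_mm("afd") if "afd" in mid_visit and "afd" in late_visit else None
    d_ri = RI_REFERENCE - float(late_visit["ri"]) if "ri" in late_visit else None
    d_pi = PI_REFERENCE - float(late_visit["pi"]) if "pi" in late_visit else None
    return DynamicIndicators(
        d_bpd_std=rate_mm("bpd"),
        d_fl_std=rate_mm("fl"),
        d_sd=(float(late_visit["sd_ratio"]) - float(mid_visit["sd_ratio"]))
        / interval_weeks,
        d_ri=d_ri,
        d_pi=d_pi,
        d_afd=d_afd,
    )


def quartile_bin(values: Sequence[float]) -> np.ndarray:
    """Label each value Q1..Q4 by empirical 25/50/75 percentile cutpoints.

    Q1 is the lowest quarter (slowest growth). Cutpoints use
    linear-interpolation percentiles; values tied with a cutpoint fall in the
    lower quartile. Fewer than 4 distinct values triggers a degenerate-quartile
    warning (all-equal input is labelled Q1 throughout).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 values to form quartiles")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in quartile binning")
    if np.unique(vals).size < 4:
        warnings.warn(
            "fewer than 4 distinct values; quartile bins are degenerate",
            UserWarning,
            stacklevel=2,
        )
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    labels = np.full(vals.shape, "Q4", dtype=object)
    labels[vals <= q75] = "Q3"
    labels[vals <= q50] = "Q2"
    labels[vals <= q25] = "Q1"
    return labels.astype(str)


# Cohort columns backing each scored reference parameter.
_CURVE_COLUMNS = {"bpd": "bpd_mid", "fl": "fl_mid", "pi": "pi_mid", "ri": "ri_mid"}


def fit_reference_curves(
    controls: pd.DataFrame, ga_domain: tuple[float, float] = DEFAULT_GA_DOMAIN
) -> dict[str, ReferenceCurve]:
    """Fit the BPD/FL/PI/RI reference curves on the control arm of a cohort."""
    if (controls["group"] != "control").any():
        raise ValueError("reference curves must be fitted on controls only")
    return {
        name: fit_reference_curve(
            controls["ga_mid"], controls[col], name, ga_domain=ga_domain
        )
        for name, col in _CURVE_COLUMNS.items()
    }


def score_cohort(
    cohort: pd.DataFrame,
    curves: Mapping[str, ReferenceCurve],
    strict: bool = False,
) -> pd.DataFrame:
    """Append deviation scores (and dynamic indicators when a late visit
    exists) to a cohort table.

    Adds ``bpd_z``, ``fl_z``, ``pi_z``, ``ri_z``, ``z_doppler``,
    ``bpd_fl_diff`` and, when late columns are present, ``d_bpd_std``,
    ``d_fl_std``, ``d_sd`` plus the quartile label ``d_bpd_quartile``.
    """
    out = cohort.copy()
    for name, col in _CURVE_COLUMNS.items():
        out[f"{name}_z"] = z_score(curves[name], out["ga_mid"], out[col], strict=strict)
    out["z_doppler"] = z_doppler(out["pi_z"], out["ri_z"])
    out["bpd_fl_diff"] = bpd_fl_diff(out["bpd_z"], out["fl_z"])
    if "ga_late" in out.columns:
        interval_weeks = (out["ga_late"] - out["ga_mid"]).astype(float) / 7.0
        if (interval_weeks <= 0).any():
            raise ValueError("late visit precedes the midtrimester visit")
        out["d_bpd_std"] = (out["bpd_late"] - out["bpd_mid"]) * 10.0 / interval_weeks
        out["d_fl_std"] = (out["fl_late"] - out["fl_mid"]) * 10.0 / interval_weeks
        out["d_sd"] = (out["sd_ratio_late"] - out["sd_ratio_mid"]) / interval_weeks
        out["d_bpd_quartile"] = quartile_bin(out["d_bpd_std"])
    return out


def curves_to_json(
    curves: Mapping[str, ReferenceCurve],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    payload = {
        name: {
            "parameter_name": c.parameter_name,
            "coefficients": [c.a0, c.a1, c.a2],
            "residual_sd": c.residual_sd,
            "ga_domain": list(c.ga_domain),
            "n_fit": c.n_fit,
        }
        for name, c in curves.items()
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2))


def curves_from_json(path: str | Path) -> dict[str, ReferenceCurve]:
    payload = json.loads(Path(path).read_text())
    payload.pop("metadata", None)
    return {
        name: ReferenceCurve(
            parameter_name=d["parameter_name"],
            a0=d["coefficients"][0],
            a1=d["coefficients"][1],
            a2=d["coefficients"][2],
            residual_sd=d["residual_sd"],
            ga_domain=tuple(d["ga_domain"]),
            n_fit=d["n_fit"],
        )
        for name, d in payload.items()
    }
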