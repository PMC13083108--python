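"""Synthetic cohort generator for VCI preterm-birth modelling.

Emulates the subject-level data structure of a retrospective cohort of
singleton pregnancies: a control arm measured on population growth/Doppler
curves, and a VCI arm in which a latent, nonnegative placental-insufficiency
severity shifts umbilical-artery resistance (PI/RI) up and femur growth down,
and raises the probability of preterm delivery through a logistic outcome
model together with maternal age and vasa previa.

Gestational age (GA) is handled in integer days throughout. Biometrics are in
cm, Doppler indices dimensionless, estimated fetal weight in grams.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GrowthCurveParams",
    "OutcomeCoefs",
    "SchemaError",
    "generate_cohort",
    "attach_late_visit",
    "write_cohort",
    "read_cohort",
    "calibrate_outcome_coefs",
    "hadlock_efw",
    "REQUIRED_COLUMNS",
    "PRETERM_CUTOFF_DAYS",
    "EARLY_TERM_CUTOFF_DAYS",
    "MIN_DELIVERY_DAYS",
]

# Delivery-category boundaries (days): preterm < 259 (37 w), early term
# 259-272, full term >= 273. Deliveries before 196 days (28 w) are outside
# the study window and are never generated.
MIN_DELIVERY_DAYS = 196
PRETERM_CUTOFF_DAYS = 259
EARLY_TERM_CUTOFF_DAYS = 273
MAX_DELIVERY_DAYS = 287


class SchemaError(ValueError):
    """A cohort table is missing a required column or violates the schema."""


@dataclass(frozen=True)
class GrowthCurveParams:
    """Quadratic mean curve value = a0 + a1*GA + a2*GA^2 (GA in days) plus
    i.i.d. Gaussian measurement/biological noise with SD ``noise_sd``."""

    a0: float
    a1: float
    a2: float
    noise_sd: float

    def mean(self, ga_days):
        ga = np.asarray(ga_days, dtype=float)
        return self.a0 + self.a1 * ga + self.a2 * ga * ga


def _quad_through(p1, p2, p3) -> tuple[float, float, float]:
    """Coefficients of the quadratic passing through three (ga, value) anchors."""
    g = np.array([p1[0], p2[0], p3[0]], dtype=float)
    v = np.array([p1[1], p2[1], p3[1]], dtype=float)
    a = np.linalg.solve(np.vander(g, 3, increasing=True), v)
    return float(a[0]), float(a[1]), float(a[2])


def _curve(p1, p2, p3, sd) -> GrowthCurveParams:
    a0, a1, a2 = _quad_through(p1, p2, p3)
    return GrowthCurveParams(a0, a1, a2, sd)


def _default_growth_curves() -> dict[str, GrowthCurveParams]:
    # Anchors chosen to reproduce typical midtrimester (around 154 d / 22 w)
    # and predelivery medians of the fetal parameters: BPD ~5.4 cm and FL
    # ~3.8 cm at 22 w rising to ~9.3 / ~7.1 cm near term; umbilical-artery
    # resistance falling with advancing gestation.
    return {
        "bpd": _curve((133, 4.30), (154, 5.40), (268, 9.30), 0.15),
        "fl": _curve((133, 3.00), (154, 3.80), (268, 7.10), 0.12),
        "ac": _curve((133, 15.80), (154, 18.00), (268, 34.00), 0.70),
        "hc": _curve((133, 17.50), (154, 20.10), (268, 33.50), 0.60),
        "pi": _curve((133, 1.25), (154, 1.15), (268, 0.85), 0.12),
        "ri": _curve((133, 0.75), (154, 0.72), (268, 0.60), 0.05),
        "sd_ratio": _curve((133, 3.40), (154, 3.00), (268, 2.15), 0.45),
        "afd": _curve((133, 4.40), (154, 4.70), (268, 4.90), 0.60),
    }


@dataclass(frozen=True)
class OutcomeCoefs:
    """Logistic model generating preterm delivery.

    logit P(preterm) = intercept + age * (maternal_age - 30)
                       + vasa_previa * I(vasa previa)
                       + latent * latent_insufficiency

    The default intercept and latent coefficient are calibrated (see
    :func:`calibrate_outcome_coefs`) so that marginal preterm rates are
    ~5.7% in controls and ~17.8% in the VCI arm.
    """

    intercept: float = -3.0154
    age: float = 0.1205
    vasa_previa: float = 2.2
    latent: float = 1.0202


@dataclass(frozen=True)
class MaternalAgeDist:
    """Truncated-normal maternal age (years)."""

    mean: float = 30.8
    sd: float = 4.2
    low: float = 22.0
    high: float = 44.0


# Per-unit-latent shifts of midtrimester measurements (same units as the
# measurement). Brain sparing: femur growth is restricted while BPD is
# relatively preserved; vascular resistance (PI/RI/SD) rises.
_DEFAULT_LATENT_EFFECT_MID: dict[str, float] = {
    "pi": 0.15,
    "ri": 0.068,
    "sd_ratio": 0.27,
    "fl": -0.135,
    "bpd": 0.0,
}

# Biometrics sharing the constitutional-size factor (Doppler indices and
# amniotic fluid do not scale with fetal size).
_SIZE_FACTOR_PARAMS = ("bpd", "fl", "ac", "hc")

# Shifts applied to the predelivery visit, where chronic insufficiency has
# accumulated: growth deficits are larger than at midtrimester.
_DEFAULT_LATENT_EFFECT_LATE: dict[str, float] = {
    "bpd": -0.10,
    "fl": -0.28,
    "ac": -0.90,
    "sd_ratio": 0.18,
}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_control: int = 105
    n_vci: int = 135
    ga_mid_range_days: tuple[int, int] = (133, 161)
    growth_curve_params: Mapping[str, GrowthCurveParams] = field(
        default_factory=_default_growth_curves
    )
    latent_effect_mid: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LATENT_EFFECT_MID)
    )
    latent_effect_late: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LATENT_EFFECT_LATE)
    )
    latent_scale: float = 1.0
    # Per-subject constitutional size: every biometric mean is scaled by
    # (1 + fetal_size_sd_frac * z_subject), so size variation is shared
    # across BPD/FL/AC/HC (and grows with gestation) rather than independent
    # measurement scatter. ~3.5% SD of size-for-GA is typical of reference
    # charts.
    fetal_size_sd_frac: float = 0.035
    # Extra widening of the predelivery measurement scatter relative to the
    # midtrimester visit.
    late_noise_multiplier: float = 1.5
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    vasa_previa_prev_vci: float = 16 / 135
    maternal_age_dist: MaternalAgeDist = field(default_factory=MaternalAgeDist)
    # P(early term | term delivery), per arm; remaining term births are full term.
    p_early_given_term_control: float = 21 / 99
    p_early_given_term_vci: float = 44 / 111
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 0 or self.n_vci < 0:
            raise ValueError("group sizes must be nonnegative")
        lo, hi = self.ga_mid_range_days
        if lo >= hi:
            raise ValueError("ga_mid_range_days is inverted")
        if lo < 120 or hi > 200:
            raise ValueError("midtrimester GA range must lie within [120, 200] days")
        for name, p in self.growth_curve_params.items():
            if p.noise_sd < 0:
                raise ValueError(f"negative noise SD for parameter {name!r}")
        if not 0.0 <= self.vasa_previa_prev_vci <= 1.0:
            raise ValueError("vasa_previa_prev_vci must lie in [0, 1]")
        if self.latent_scale < 0:
            raise ValueError("latent_scale must be nonnegative")


# Columns every cohort file must provide (late-visit columns are optional).
REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "maternal_age",
    "vasa_previa",
    "ga_mid",
    "bpd_mid",
    "fl_mid",
    "ac_mid",
    "hc_mid",
    "pi_mid",
    "ri_mid",
    "sd_ratio_mid",
    "afd_mid",
    "ga_delivery",
    "delivery_category",
    "preterm",
)

LATE_COLUMNS: tuple[str, ...] = (
    "ga_late",
    "bpd_late",
    "fl_late",
    "ac_late",
    "sd_ratio_late",
    "efw",
)

FLAG_COLUMNS: tuple[str, ...] = (
    "vasa_previa",
    "preterm",
    "hypertension",
    "gdm",
    "hypothyroidism",
    "cesarean",
    "low_birth_weight",
    "composite_adverse",
)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def delivery_category(ga_delivery) -> np.ndarray:
    """Map delivery GA (days) to preterm / early_term / full_term labels."""
    ga = np.asarray(ga_delivery)
    out = np.where(
        ga < PRETERM_CUTOFF_DAYS,
        "preterm",
        np.where(ga < EARLY_TERM_CUTOFF_DAYS, "early_term", "full_term"),
    )
    return out


def generate_cohort(config: SimConfig | None = None) -> pd.DataFrame:
    """Draw a complete midtrimester cohort (no late visit yet).

    Deterministic given ``config.seed``. Controls are sampled on the
    population curves plus noise; VCI subjects additionally receive a
    half-normal latent insufficiency severity that perturbs their Doppler and
    femur measurements and feeds the preterm-generating logistic model.
    """
    if config is None:
        config = SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_control + config.n_vci
    group = np.array(["control"] * config.n_control + ["vci"] * config.n_vci)
    is_vci = group == "vci"

    ad = config.maternal_age_dist
    age = rng.normal(ad.mean, ad.sd, size=n).clip(ad.low, ad.high).round(1)

    vasa = np.zeros(n, dtype=int)
    vasa[is_vci] = rng.random(config.n_vci) < config.vasa_previa_prev_vci

    latent = np.zeros(n)
    latent[is_vci] = np.abs(rng.normal(0.0, config.latent_scale, config.n_vci))

    lo, hi = config.ga_mid_range_days
    ga_mid = rng.integers(lo, hi + 1, size=n)

    size_z = rng.normal(0.0, 1.0, n)
    cols: dict[str, np.ndarray] = {}
    for name, curve in config.growth_curve_params.items():
        mean = curve.mean(ga_mid)
        if name in _SIZE_FACTOR_PARAMS:
            mean = mean * (1.0 + config.fetal_size_sd_frac * size_z)
        shift = config.latent_effect_mid.get(name, 0.0) * latent
        vals = mean + shift + rng.normal(0.0, curve.noise_sd, n)
        cols[f"{name}_mid"] = np.maximum(vals, 0.01).round(2)

    oc = config.outcome_coefs
    p_preterm = _expit(
        oc.intercept + oc.age * (age - 30.0) + oc.vasa_previa * vasa + oc.latent * latent
    )
    preterm = (rng.random(n) < p_preterm).astype(int)

    ga_delivery = np.empty(n, dtype=int)
    pre_idx = preterm == 1
    ga_delivery[pre_idx] = rng.integers(
        MIN_DELIVERY_DAYS, PRETERM_CUTOFF_DAYS, size=int(pre_idx.sum())
    )
    term_idx = ~pre_idx
    p_early = np.where(
        is_vci, config.p_early_given_term_vci, config.p_early_given_term_control
    )
    early = rng.random(n) < p_early
    et = term_idx & early
    ft = term_idx & ~early
    ga_delivery[et] = rng.integers(
        PRETERM_CUTOFF_DAYS, EARLY_TERM_CUTOFF_DAYS, size=int(et.sum())
    )
    ga_delivery[ft] = rng.integers(
        EARLY_TERM_CUTOFF_DAYS, MAX_DELIVERY_DAYS + 1, size=int(ft.sum())
    )

    # Descriptive comorbidity / outcome flags (not used by the prediction
    # models; rates mirror the two-arm contrasts of the emulated population).
    hypertension = (rng.random(n) < np.where(is_vci, 0.148, 0.057)).astype(int)
    gdm = (rng.random(n) < np.where(is_vci, 0.148, 0.124)).astype(int)
    hypothyroidism = (rng.random(n) < np.where(is_vci, 0.200, 0.219)).astype(int)
    cesarean = (rng.random(n) < np.where(is_vci, 0.75, 0.40)).astype(int)
    cesarean[vasa == 1] = 1
    low_birth_weight = (
        rng.random(n) < np.where(pre_idx, 0.60, 0.03)
    ).astype(int)
    composite_adverse = (
        (low_birth_weight == 1)
        | (rng.random(n) < np.where(is_vci, 0.10, 0.05))
    ).astype(int)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "group": group,
            "maternal_age": age,
            "vasa_previa": vasa,
            "ga_mid": ga_mid,
            "bpd_mid": cols["bpd_mid"],
            "fl_mid": cols["fl_mid"],
            "ac_mid": cols["ac_mid"],
            "hc_mid": cols["hc_mid"],
            "pi_mid": cols["pi_mid"],
            "ri_mid": cols["ri_mid"],
            "sd_ratio_mid": cols["sd_ratio_mid"],
            "afd_mid": cols["afd_mid"],
            "ga_delivery": ga_delivery,
            "delivery_category": delivery_category(ga_delivery),
            "preterm": preterm,
            "hypertension": hypertension,
            "gdm": gdm,
            "hypothyroidism": hypothyroidism,
            "cesarean": cesarean,
            "low_birth_weight": low_birth_weight,
            "composite_adverse": composite_adverse,
            "latent_insufficiency": latent.round(6),
            "fetal_size_z": size_z.round(6),
        }
    )
    return table


def hadlock_efw(bpd_cm, ac_cm, fl_cm) -> np.ndarray:
    """Estimated fetal weight (g), Hadlock BPD/AC/FL formula.

    log10(EFW) = 1.335 - 0.0034*AC*FL + 0.0316*BPD + 0.0457*AC + 0.1623*FL
    Monotone increasing in each biometric over the clinical range.
    """
    bpd = np.asarray(bpd_cm, dtype=float)
    ac = np.asarray(ac_cm, dtype=float)
    fl = np.asarray(fl_cm, dtype=float)
    log10_efw = 1.335 - 0.0034 * ac * fl + 0.0316 * bpd + 0.0457 * ac + 0.1623 * fl
    return np.power(10.0, log10_efw)


def attach_late_visit(
    cohort: pd.DataFrame, config: SimConfig | None = None
) -> pd.DataFrame:
    """Add a predelivery ultrasound visit 0-7 days before delivery.

    Late biometrics extrapolate the population curves to the late GA, with the
    VCI latent-insufficiency shifts scaled for accumulated growth deficit, and
    EFW derived from the late biometrics via the Hadlock formula.
    """
    if config is None:
        config = SimConfig()
    config.validate()
    if "ga_delivery" not in cohort.columns:
        raise SchemaError("cohort is missing required column 'ga_delivery'")
    rng = np.random.default_rng(np.uint32(config.seed) + np.uint32(7))
    out = cohort.copy()
    n = len(out)
    latent = out.get(
        "latent_insufficiency", pd.Series(np.zeros(n), index=out.index)
    ).to_numpy(dtype=float)
    size_z = out.get(
        "fetal_size_z", pd.Series(np.zeros(n), index=out.index)
    ).to_numpy(dtype=float)
    ga_late = out["ga_delivery"].to_numpy() - rng.integers(0, 8, size=n)
    out["ga_late"] = ga_late
    curves = config.growth_curve_params
    mult = config.late_noise_multiplier
    for name in ("bpd", "fl", "ac"):
        curve = curves[name]
        mean = curve.mean(ga_late) * (1.0 + config.fetal_size_sd_frac * size_z)
        shift = config.latent_effect_late.get(name, 0.0) * latent
        vals = mean + shift + rng.normal(0.0, mult * curve.noise_sd, n)
        out[f"{name}_late"] = np.maximum(vals, 0.01).round(2)
    sd_curve = curves["sd_ratio"]
    sd_shift = config.latent_effect_late.get("sd_ratio", 0.0) * latent
    out["sd_ratio_late"] = np.maximum(
        sd_curve.mean(ga_late) + sd_shift
        + rng.normal(0.0, mult * sd_curve.noise_sd, n),
        0.01,
    ).round(2)
    out["efw"] = hadlock_efw(out["bpd_late"], out["ac_late"], out["fl_late"]).round(0)
    return out


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    """Write a cohort CSV (flags as 0/1, floats to 6 significant digits)."""
    cohort.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating the required schema columns.

    Unknown extra columns are preserved; downstream stages ignore them.
    """
    table = pd.read_csv(path, comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"cohort file is missing required column {col!r}")
    for col in FLAG_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype(int)
    return table


def _marginal_rates(config: SimConfig, n_mc: int = 400_000, seed: int = 12345):
    """Deterministic Monte-Carlo marginal preterm rates (control, VCI)."""
    rng = np.random.default_rng(seed)
    ad = config.maternal_age_dist
    age = rng.normal(ad.mean, ad.sd, n_mc).clip(ad.low, ad.high)
    oc = config.outcome_coefs
    base = oc.intercept + oc.age * (age - 30.0)
    rate_control = float(_expit(base).mean())
    vasa = rng.random(n_mc) < config.vasa_previa_prev_vci
    latent = np.abs(rng.normal(0.0, config.latent_scale, n_mc))
    rate_vci = float(_expit(base + oc.vasa_previa * vasa + oc.latent * latent).mean())
    return rate_control, rate_vci


def calibrate_outcome_coefs(
    config: SimConfig | None = None,
    target_control: float = 0.057,
    target_vci: float = 0.178,
    tol: float = 1e-4,
) -> OutcomeCoefs:
    """Calibrate the outcome intercept and latent coefficient by bisection.

    The intercept is bisected so the marginal control preterm rate matches
    ``target_control``; given that intercept, the latent coefficient is
    bisected so the marginal VCI rate (including the vasa-previa mixture)
    matches ``target_vci``. Rates are evaluated by a large fixed-seed
    Monte-Carlo integral, so the procedure is deterministic.
    """
    if config is None:
        config = SimConfig()

    def with_coefs(intercept, latent):
        return dataclasses.replace(
            config,
            outcome_coefs=dataclasses.replace(
                config.outcome_coefs, intercept=intercept, latent=latent
            ),
        )

    lo, hi = -8.0, 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        rate, _ = _marginal_rates(with_coefs(mid, config.outcome_coefs.latent))
        if rate < target_control:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol / 10:
            break
    intercept = 0.5 * (lo + hi)

    lo, hi = 0.0, 6.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _, rate = _marginal_rates(with_coefs(intercept, mid))
        if rate < target_vci:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol / 10:
            break
    latent_coef = 0.5 * (lo + hi)
    return dataclasses.replace(
        config.outcome_coefs, intercept=intercept, latent=latent_coef
    )
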