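# Methods

`vcipreterm` implements a midtrimester growth-deviation approach to
predicting preterm birth (delivery at >= 28 and < 37 completed weeks; >= 196
and < 259 days) in pregnancies with velamentous cord insertion (VCI). This
note records the statistical model, the synthetic-data design, the numerical
choices, and the known limitations.

## The deviation metrics

Reference curves for biparietal diameter (BPD), femur length (FL) and the
umbilical-artery pulsatility and resistance indices (PI, RI) are quadratic
polynomials in exact gestational age (GA, integer days), fitted by ordinary
least squares to the control arm over the domain 130–200 days. A single
homoscedastic residual SD per parameter (df = n − 3) converts an observation
into a GA-standardised deviation:

    Z = (observed − predicted at the same GA) / residual SD

Two composites summarise the deviations:

* `Z_doppler = sqrt((PI_z² + RI_z²)/2)` — a nonnegative, directionless
  magnitude of Doppler deviation. PI and RI are strongly collinear
  (r > 0.7), so their joint magnitude replaces two separate predictors.
* `BPD_FL_diff = BPD_z − FL_z` — head-to-femur discordance. Placental
  insufficiency restricts femur growth while sparing head growth
  ("brain-sparing"), so positive discordance marks the at-risk pattern.

Out-of-domain GA extrapolates the quadratic with a warning by default; a
strict mode rejects instead. Because OLS residuals with an intercept sum to
zero, in-sample control Z-scores have mean 0 (tested to 1e-8) and SD ~1.

Two-visit dynamic indicators follow the convention
`(late − early) / interval in weeks`, with biometric rates in mm/week, plus
the reference-anchored `dRI = 0.55 − late RI` and `dPI = 0.78 − late PI`
(literature constants for late-gestation umbilical-artery indices, taken as
given). The standardised BPD growth rate is additionally coded into
quartiles Q1–Q4 (Q1 = slowest growth; linear-interpolation percentile
cutpoints, ties to the lower quartile) because its association with preterm
birth is non-linear.

## The four prediction models

All models are fitted on the VCI arm only (preterm as outcome). Models 1–3
use a three-step pipeline: univariate logistic screening at P <= 0.10 (Wald),
L1-penalised (LASSO) selection with the penalty chosen by 10-fold
cross-validated deviance (minimum rule, seeded folds, predictors standardised
inside the selection only), and a final maximum-likelihood logistic fit with
Wald 95% CIs. Model 4 is prespecified — maternal age, vasa previa,
`BPD_FL_diff`, `Z_doppler` — with no screening or shrinkage, so it is
estimable from midtrimester data alone.

Candidate pools: Model 1 (midtrimester baseline) — age, advanced-age flag
(>= 35 years, the obstetric convention), comorbidity count, mid BPD/FL/RI;
Model 2 (predelivery benchmark) — late BPD, FL, AC, S/D and estimated fetal
weight (EFW); Model 3 — all static mid and late parameters plus the
ΔBPD quartile dummies (Q2–Q4 vs Q1).

Numerical choices: the L1 solver is a proximal-Newton coordinate-descent
(glmnet-style) routine, JIT-compiled with numba; the intercept is never
penalised. Its zero-penalty limit agrees with the unpenalised MLE to ~1e-8.
The penalty grid is 10 points, log-spaced over C in [10^-2.5, 10^2] on the
standardised scale; the minimum-deviance rule (not 1-SE) picks the penalty.
If selection is empty, the model falls back to the screened set; if
screening retains nothing, to the best-screening candidate — so bootstrap
refits on degenerate resamples always produce a model. (Quasi-)complete
separation in the final fit falls back to a lightly ridge-penalised Newton
fit (lambda = 0.1 on the standardised scale, intercept unpenalised), flagged
in the output with CIs suppressed.

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counted 1/2
(identical to the trapezoidal empirical ROC area). The operating point
maximises the Youden index over observed scores, ties broken toward the
lowest cutoff (favouring sensitivity). Calibration uses the Hosmer–Lemeshow
deciles-of-risk test (g = 10, df = g − 2, quantile groups with ties kept
together, degenerate groups merged). Internal validation resamples subjects
with replacement, re-runs the *entire* construction pipeline per resample,
and reports the mean and 2.5/97.5 percentiles of the resample-apparent AUCs;
a Harrell optimism-corrected variant is available via a switch.
Single-class resamples are redrawn and counted.

## Risk stratification

Model-4 probabilities cut the VCI arm into low (< 0.1), moderate (0.1–0.3,
boundaries inclusive) and high (> 0.3) tiers. The validation battery:
one-sided Cochran–Armitage trend test (scores 1,2,3, increasing-risk
direction), Spearman rank correlation between probability and outcome,
overall 3x2 Pearson chi-square (df 2, no continuity correction),
Fisher exact comparison of the low tier against controls (p by
hypergeometric enumeration; OR reported as the unconditional sample
cross-product ratio with a Woolf logit CI; Haldane–Anscombe 0.5 correction
for the CI only when a cell is zero, the raw OR reported as 0/inf), and
Clopper–Pearson exact 95% intervals per tier.

## Time-to-event analysis

The time scale is GA at delivery in days; event codes are 0 = censored,
1 = preterm, 2 = term delivery (competing). Kaplan–Meier incidence (term
treated as censoring, Greenwood CIs, lifelines) is reported at the landmark
days 224/238/252/259 (32/34/36/37 weeks), evaluated right-continuously.
The group contrast uses the log-rank test and a Cox model with Breslow tie
handling (many tied delivery days at day resolution). Competing risks use
hand-rolled Aalen–Johansen CIFs — chosen over a library implementation so
the conservation identity CIF1 + CIF2 + S = 1 holds to float precision at
every jump and the Greenwood-type variance is explicit. Gray's test (rho=0)
is computed as the weighted log-rank statistic on the subdistribution risk
set with inverse-probability-of-censoring weights (Geskus reweighting);
with no censoring the weights are 1, and with no competing events it reduces
exactly to the log-rank statistic (tested to 1e-6).

A structural remark: on the GA time scale every preterm event (< 259 days)
precedes every term delivery (>= 259 days), so competing-event reweighting
never affects risk sets at preterm event times and Gray's statistic
coincides with the log-rank statistic on such data. The competing-risk
machinery is still exercised (and tested) on general inputs with interleaved
causes and censoring.

## Decision curve analysis

Net benefit at threshold Pt is `TP/n − FP/n · Pt/(1−Pt)` with subjects
classified positive when predicted probability >= Pt (ties positive; the rule
is switchable). The default grid is 0.05 to 0.50 in steps of 0.05. Treat-all
has the closed form `pi − (1−pi)·Pt/(1−Pt)` (zero exactly at Pt = prevalence)
and treat-none is identically zero.

## Descriptive statistics

2x2 contingency contrasts use the Yates-corrected chi-square; r x c tables
use the plain Pearson statistic (these two dialects reproduce the published
worked examples to 2 decimals); sparse tables trigger a warning rather than
an automatic exact test. Continuous variables are routed by Shapiro–Wilk at
alpha 0.05 in both groups to either mean +/- SD with Welch's t-test or
median (P25, P75) with the Mann–Whitney U-test (midranks; exact p for small
untied samples, continuity-corrected normal approximation otherwise).

## The synthetic cohort generator

No patient-level data are available, so the generator emulates the study's
structure: 105 controls and 135 VCI singleton pregnancies, a midtrimester
scan at 21 +/- 2 weeks (GA uniform on 133–161 days) and a predelivery scan
0–7 days before delivery, delivery at >= 196 days.

* **Growth structure.** Each parameter follows a quadratic mean curve in GA
  anchored at typical midtrimester and near-term values (e.g. BPD 5.4 cm at
  154 days, 9.3 cm at 268 days). A per-subject constitutional-size factor
  (normal, 3.5% SD, multiplicative on BPD/FL/AC/HC at both visits) makes
  biometric variation shared across parameters and growing with gestation —
  without it, independent measurement noise lets late-visit models separate
  the outcome perfectly, which no real cohort shows. Measurement noise is
  Gaussian per parameter (e.g. BPD 0.15 cm at mid), widened 1.5x at the
  late visit. EFW is the Hadlock BPD/AC/FL formula applied to the late
  biometrics.
* **Latent insufficiency.** VCI subjects draw a nonnegative half-normal
  (scale 1) placental-insufficiency severity that raises PI/RI/S-D and
  depresses FL at the mid visit (PI +0.15, RI +0.068, S/D +0.27, FL −0.135
  per unit), with larger accumulated growth deficits at the late visit
  (BPD −0.10, FL −0.28, AC −0.90 cm per unit). Controls have severity 0.
  The half-normal gives the right-skewed severity expected when a minority
  of pregnancies are meaningfully affected.
* **Outcome model.** Preterm delivery follows a logistic model in centred
  maternal age (log-OR 0.1205/year), vasa previa (log-OR 2.2; prevalence
  16/135, VCI arm only) and the latent severity. The intercept (−3.0154)
  and latent coefficient (1.0202) were calibrated by bisection on
  deterministic Monte-Carlo integrals so the marginal preterm rates are
  5.7% (controls) and 17.8% (VCI). Preterm deliveries land uniformly on
  196–258 days; term deliveries split into early term (259–272) and full
  term (273–287) with per-arm early-term fractions matching the emulated
  cohort's category structure.
* **What it does not emulate.** Within-subject longitudinal correlation of
  Doppler indices, GA-dependent measurement error, informative scan timing,
  missing data (the design is complete-case), or deliveries before 28 weeks.
  Passing tests therefore demonstrate the pipeline's statistical
  correctness and its behaviour under the assumed data-generating structure,
  not clinical performance on real cohorts.

The simulation-truth columns `latent_insufficiency` and `fetal_size_z` are
written into generated cohorts for parameter-recovery testing; the analysis
pipeline never reads them.

A consequence of calibrating the latent effect through the marginal VCI
rate: discrimination attainable by any midtrimester model is bounded by the
information in (age, vasa previa, latent severity), and the deviation-index
model approaches that ceiling (mean apparent AUC ~0.75–0.78 at n = 135)
rather than any particular published value. The predelivery models sit far
higher (~0.96–0.99) because the late scan is conditioned to fall within a
week of delivery. The bootstrap-mean AUC of the combined mid+late model
slightly *exceeds* the predelivery benchmark under these conditions: its
candidate pool contains every informative late parameter, and
resample-apparent AUCs reward the larger pool. An observed ordering with the
combined model below the benchmark can arise from a particular sample's
selection path but is not a stable property of the generating structure.

## Problem sizes used in the test suite

Property suites run at sizes chosen to keep Monte-Carlo error well inside
the asserted margins on a single CPU: rate calibration over 300 seeds;
coefficient recovery on 200 cohorts of n = 2,000; Hosmer–Lemeshow type-I
error over 500 well-specified simulations of n = 1,000; Fisher p vs
enumeration for every 2x2 table with total n <= 30; bootstrap seed
stability at B = 1,000; the model-ordering study over 50 cohorts of 240
subjects with B = 100 pipeline-refitting resamples per model.
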