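# vcipreterm

Midtrimester growth-deviation modelling of preterm-birth risk in
velamentous cord insertion (VCI) pregnancies.

In VCI the umbilical cord inserts into the fetal membranes instead of the
placental mass, leaving vessels unprotected by Wharton's jelly and raising
the risk of preterm delivery (here: >= 28 and < 37 weeks). Whether — and how
early — that risk can be quantified matters for delivery-timing decisions:
predelivery ultrasound predicts well but leaves no time to act, while a
midtrimester (21 ± 2 weeks) assessment gives ~16 weeks of warning.

This package implements the full analysis pipeline for that question, aimed
at biostatisticians and perinatal epidemiologists:

1. **Reference curves and deviation scores.** Quadratic-in-GA reference
   curves for BPD, FL, PI and RI fitted to a control population (130–200
   days), and per-subject standardised deviations
   `Z = (observed − predicted)/residual SD`, combined into
   `Z_doppler = sqrt((PI_z² + RI_z²)/2)` (Doppler deviation magnitude) and
   `BPD_FL_diff = BPD_z − FL_z` (brain-sparing head-to-femur discordance).
2. **Four logistic prediction models.** Models 1–3 via univariate screening
   (P ≤ 0.10) → cross-validated LASSO selection → ML logistic fit; Model 4
   prespecified on maternal age, vasa previa, `BPD_FL_diff` and `Z_doppler`
   (midtrimester data only).
3. **Evaluation.** Mann–Whitney AUC, Youden operating point,
   Hosmer–Lemeshow calibration (g = 10), and bootstrap internal validation
   that refits the whole pipeline per resample.
4. **Three-tier risk stratification** of Model-4 probabilities (<0.1 /
   0.1–0.3 / >0.3) with its validation battery: Cochran–Armitage trend,
   Spearman correlation, overall chi-square, Fisher exact low-vs-control
   comparison, Clopper–Pearson exact intervals.
5. **Time-to-event analysis.** Kaplan–Meier cumulative incidence with
   landmark tables (32/34/36/37 weeks), log-rank, Cox HR (Breslow ties),
   Aalen–Johansen competing-risk CIFs and Gray's test.
6. **Decision curve analysis.** Net benefit `TP/n − FP/n·Pt/(1−Pt)` against
   treat-all/treat-none over thresholds 5–50%.
7. **A synthetic cohort generator** (105 controls / 135 VCI, calibrated
   preterm rates 5.7% / 17.8%, latent placental-insufficiency structure)
   that makes every stage testable without patient data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```bash
vcipreterm simulate --seed 42 --out cohort.csv
vcipreterm score --cohort cohort.csv --curves curves.json --out scores.csv
vcipreterm evaluate --model 4 --scores scores.csv --bootstrap 1000 --out eval4.json
vcipreterm stratify --scores scores.csv --out strat.json
vcipreterm survival --cohort cohort.csv --out incidence.csv
```

prints (seed 42):

```
wrote 240 subjects to cohort.csv
scored 240 subjects -> scores.csv
model 4: AUC=0.883 bootstrap=0.898 CI=(0.810, 0.974)
    tier probability_range  n  proportion  events  event_rate   ci_low  ci_high
     low              <0.1 95    0.703704       5    0.052632 0.017308 0.118563
moderate           0.1-0.3 18    0.133333       1    0.055556 0.001406 0.272944
    high              >0.3 22    0.162963      14    0.636364 0.406577 0.828021
log-rank chi2=2.97 (p=0.0846); Cox HR=2.03 (0.89-4.60); Gray chi2=2.97 (p=0.0846)
```

Reading this: on this simulated cohort the prespecified midtrimester model
discriminates preterm from term VCI deliveries with AUC 0.88 (bootstrap mean
0.90, percentile CI 0.81–0.97). Stratifying its predicted probabilities at
0.1 and 0.3 puts 95 of 135 VCI pregnancies in the low tier with a 5.3%
preterm rate (close to a control population), while the 22 high-tier
pregnancies carry a 63.6% rate — the monotone gradient the tiers are
designed to show, with Clopper–Pearson 95% bounds per tier. The survival
line compares arms on the gestational-age scale: VCI carries about twice
the preterm hazard of controls in this replicate (HR 2.03), not significant
at n = 240 for this seed. Equivalently from Python:
`vcipreterm.run_pipeline(vcipreterm.PipelineConfig(seed=42))`.

The same machinery reproduces published worked examples exactly, e.g.
`vcipreterm tabletest --chisq2x2 42 63 107 28` prints `chi2=37.02` (cesarean
rates 40.0% vs 79.3% in 105 controls vs 135 VCI), and
`--fisher 4 58 6 99` prints `OR=1.14 (0.31-4.20)`.

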