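# neogrowth

Nutrition audit and postnatal-growth analysis for **moderately preterm
infants** (30–33 weeks of gestation). The package is aimed at
neonatologists and clinical epidemiologists auditing NICU feeding
practice: it turns sparse bedside records — parenteral prescriptions
and enteral milk volumes observed at days of life (DOL) 1, 3, 7 and
14 — into cumulative nutrient doses, scores them against guideline
targets, quantifies growth faltering, and relates early nutrition to
the change in weight Z-score during the hospital stay.

## What it computes

**Sparse-sampling cumulative intake.** Assuming intake progresses
linearly between the four observation days, the cumulative DOL1–14
intake is a fixed weighted sum of the observed rates:

```
cumulative = 1.5·r(1) + 3·r(3) + 5.5·r(7) + 4·r(14)
```

The weights are the exact trapezoid day-sum coefficients, so the
formula reproduces the plain 14-day sum exactly for any piecewise-linear
trajectory, and `validate_estimator` measures its r² against full daily
collection on arbitrary trajectories. The cumulative deficit against a
guideline target dose *T* (g/kg/d or kcal/kg/d) is `14·T − cumulative`.

**Guideline compliance.** Three criteria, compared with `≥` exactly:
amino acids (AA) ≥ 1.5 g/kg/d started on DOL1, AA ≥ 3.5 g/kg/d attained
by DOL7, and energy ≥ 120 kcal/kg/d by DOL7. Unit questionnaires
(intended practice) are compared side by side with record-derived
actual practice per gestational-age stratum.

**Growth.** Z-scores `z = (x − μ(sex, GA)) / σ(sex, GA)` (or LMS)
against a pluggable reference chart; SGA = birth weight below the 10th
percentile (z < −1.2816); EUGR = not born SGA but below the 10th
percentile at 36 weeks postconceptional age or discharge;
ΔZ = z₃₆ − z_birth; maximal postnatal weight loss in % of birth weight.

**Cohort analysis.** Candidate covariates are screened by simple
regression (p < 0.10) and survivors enter a multivariable OLS; each term
is reported with its coefficient, partial correlation
`r = sign(t)·√(t²/(t²+df))` and p-value. Cumulative AA intake enters as
a tertile score (1–3).

**Synthetic cohorts.** A seeded generator produces cohorts with the
published structure (276 infants, 64/68/76/68 per GA week, AA
1.1 ± 0.7 g/kg/d at DOL1 rising to 2.9 ± 0.9 at DOL7, cumulative
37.0 ± 8.3 g/kg AA and 1201 ± 166 kcal/kg energy, birth-weight Z
−0.17 ± 0.88), so every stage is testable without clinical data.

## Worked example

```python
from neogrowth import (SparseIntakeObservations, estimate_cumulative,
                       cumulative_deficit, DeltaZModel,
                       generate_cohort, CohortSpec)

obs = SparseIntakeObservations(1.1, 2.0, 2.9, 3.2, nutrient="aa")
cum = estimate_cumulative(obs)           # 1.5·1.1 + 3·2.0 + 5.5·2.9 + 4·3.2
d = cumulative_deficit(cum, target_dose=3.5)
print(f"cumulative AA intake DOL1-14: {cum:.1f} g/kg")
print(f"cumulative AA deficit vs 3.5 g/kg/d: {d.cumulative_deficit:.1f} g/kg")

cohort = generate_cohort(CohortSpec(seed=1))
res = DeltaZModel.from_dataframe(cohort.growth, "delta_z",
                                 ["tertile_aa", "full_feed_dol"]).fit()
print(res.summary())
```

prints

```
cumulative AA intake DOL1-14: 36.4 g/kg
cumulative AA deficit vs 3.5 g/kg/d: 12.6 g/kg

Screened multiple linear regression: delta_z
n = 276, screen alpha = 0.1, candidates = 2, retained = 2
model r2 = 0.084, model p = 6.04e-06

variable                              coef   r_partial           p
tertile_aa                           0.116        0.21    0.000402
full_feed_dol                       -0.013       -0.20     0.00079
```

The infant accrued 36.4 g/kg of amino acids over the first fortnight,
12.6 g/kg short of the 3.5 g/kg/d guideline dose. On the synthetic
cohort, each tertile step of cumulative AA intake improves the weight
ΔZ-score by ≈0.12, and each extra day to full enteral feeding costs
≈0.01 Z — both recovered close to the generator's configured effects
(0.13 and −0.01).

A CLI mirrors the library: `neogrowth simulate | intake | comply |
growth | analyze | validate-estimator | run`, e.g.

```sh
neogrowth run --seed 11 --out results/run
```

writes the full report bundle (intake, compliance, growth and
regression tables plus a reproducibility manifest).

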