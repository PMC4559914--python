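# Methods

## The sparse-sampling cumulative-intake estimator

Bedside nutrition records in routine audits carry nutrient rates
(amino acids in g/kg/d, energy in kcal/kg/d) at days of life 1, 3, 7
and 14 only. Under the assumption that intake progresses linearly
within the intervals DOL1–3, 3–7 and 7–14, the sum of the 14 daily
rates collapses to a weighted sum of the four observed ones with
weights (1.5, 3, 5.5, 4). These are ordinary trapezoid day-sum
coefficients: writing the daily value on day *d* as the linear
interpolant of the knots and summing *d* = 1…14 attributes
1 + ½ = 1.5 units to the DOL1 knot, ½ + 1 + 1.5 = 3 to DOL3,
1.5 + 1 + 3 = 5.5 to DOL7 and 3 + 1 = 4 to DOL14. Two consequences are
tested as exact properties: the weights sum to the 14-day horizon (a
constant rate *c* gives 14*c*), and the estimator equals the daily sum
*exactly* for every piecewise-linear trajectory.
`SparseScheme.from_days` generalises the weights to any knot set and
horizon; the default scheme implements the printed weights verbatim.

On real trajectories the assumption fails on the 10 non-knot days, and
`validate_estimator` quantifies the damage by regressing true daily
sums on sparse estimates (r², slope, intercept, mean absolute error).
Because the sparse estimate is computed from the knot-day values, which
carry no interpolation error, the validation r² is essentially the
variance ratio `Var(signal) / (Var(signal) + Var(non-knot noise))`.

The cumulative deficit is `target_dose × horizon − cumulative_intake`.
Deficits are deliberately not clamped at zero: clamping would break the
identity `intake + deficit = target × horizon`, which is asserted
bit-for-bit in its defining form. A missing sampling day raises by
default; `SparseIntakeObservations.from_partial(..., locf=True)`
optionally carries the last observation forward with a warning.

## Intake arithmetic

Parenteral energy uses configurable conversion factors, default
3.4/4.0/9.0 kcal per g of dextrose/amino acids/lipid (conventional
parenteral values; units differ mainly in the dextrose figure, hence
the knob). Enteral intake assumes human milk of 64 kcal/dl and
1.4 g/dl protein unless another composition or a per-dl fortifier
increment is supplied. Parenteral amino acids and milk protein are
pooled into one protein axis because the cumulative analysis mixes both
routes; energy on days with both routes is total energy, with the
parenteral fraction retained for inspection. Fluid volumes,
electrolytes, minerals and osmolarity are out of scope.

## Compliance scoring

Criteria i–iii use `≥` with no tolerance band (clinical doses are
charted to 0.1 g/kg). "Attained by DOL7" is evaluated on the DOL7
observation — the sampling scheme records nothing on days 4–6, so
attainment there is unknowable from the data model. Lipid timing uses
the recorded start day (the sampled rates skip DOL2). Criterion iii
energy is total-route energy by default (configurable); per-GA target
overrides hook in through `GuidelineTargets.per_ga_overrides` for
guideline tables that differentiate 30–31 from 32–33 weeks.

## Growth reference and classification

The reference chart is pluggable via a long-format CSV
(`sex, ga_days, measure` + `mean,sd` or `L,M,S`; dialect auto-detected).
Parameters are interpolated linearly in GA (days). Under LMS,
`z = ((x/M)^L − 1)/(L·S)` with the `L→0` logarithmic limit. The
bundled default is a **synthetic** parametric chart — a smooth weight
median in GA with a constant 13 % coefficient of variation (5.5 % for
length, 4.5 % head circumference, ±3 % by sex) spanning 24–44 weeks.
It is anatomically plausible but is not a clinical reference; any
published chart in the CSV schema should replace it for real data.
Because Z-score statistics are invariant to the chart used to
back-transform synthetic cohorts, no package result depends on the
synthetic chart's exact medians.

The 10th-percentile cutoff is the normal quantile z < −1.2816 (strict
inequality), identical under mean/SD and LMS since the LMS z is a
normal score. EUGR is defined as *not* SGA at birth **and** below the
10th percentile at 36 weeks PCA/DC; SGA-and-below and EUGR therefore
partition the below-percentile infants exactly, an identity asserted by
count on generated cohorts. Measurements taken at discharge before 36
weeks are Z-scored at the actual PCA of measurement.

## Screen-then-fit regression

Candidates are screened one at a time by simple linear regression; only
slope p < 0.10 survivors enter the multivariable OLS (no
multiple-testing correction is applied at the screen — the procedure is
reported as-is, not optimised). Tertiles enter as a numeric 1–3 score,
i.e. a linear trend across thirds; ties at a quantile cut take the
lower tertile (deterministic). The partial correlation is computed
from the term's t statistic, `r = sign(t)·√(t²/(t²+df_resid))`, which
for a single predictor reproduces the simple correlation exactly (a
tested identity). Exact collinearity aborts the fit naming the
offending columns. The paired birth-vs-36-week comparison is a paired
t test (a two-timepoint repeated-measures analysis reduces to it);
zero-variance differences return a flagged degenerate result.
`group_compare` dispatches chi-square → Fisher's exact on 2×2 tables
when any expected cell is below 5 or any observed cell is empty, and
ANOVA vs rank tests by a caller-supplied normality flag.

## Synthetic cohort generator

The generator's defaults are the study conditions, not free dials:

| quantity | default | basis |
|---|---|---|
| n, GA distribution | 276; 64/68/76/68 at 30/31/32/33 wk | cohort table |
| birth-weight Z | Normal(−0.17, 0.88) | cohort table |
| AA knots (DOL1/3/7/14), g/kg/d | means 1.1/1.7/2.9/3.575, SDs 0.7/0.77/0.9/1.0 | DOL1 and DOL7 published; DOL3/DOL14 calibrated (below) |
| energy knots, kcal/kg/d | means 40/70/94/103.5, SDs 15/16/18/20 | DOL7 published; rest calibrated |
| daily noise (non-knot days) | 0.44 g/kg/d; 10 kcal/kg/d | sets validation r² ≈ 0.973 / 0.965 |
| ΔZ model | −0.943 + 0.13·tertile − 0.01·full-feed-day + N(0, 0.45) | published effect sizes; intercept gives mean ΔZ −0.80 |
| milestones | enteral start N(1.7, 1.2); full feeds N(11.7, 6.9), rounded, ≥ start | published means |
| practice probabilities | PN DOL1 0.92, CVL 0.76, AA DOL1 0.93, lipids ≤ DOL2 0.47 | published rates |

**Knot calibration.** The DOL3 and DOL14 rate moments are not
published. DOL3 means interpolate the published DOL1→DOL7 trend and
DOL14 means are set so the weighted (1.5/3/5.5/4) sum of knot means
equals the published cumulative means (37.0 g/kg, 1201 kcal/kg); knot
SDs interpolate/extrapolate the published ones. This is calibration,
not ground truth. Knots are drawn from an equicorrelated multivariate
normal (one shared per-infant effect plus independent deviations); the
common correlation is *solved* from the marginal SDs so the cumulative
SD matches the published 8.3 g/kg and 166 kcal/kg — giving ρ ≈ 0.21
(AA) and ρ ≈ 0.20 (energy). A fixed correlation (e.g. 0.6) cannot
simultaneously honour the published marginal SDs and the published
cumulative SDs; solving for it honours both, and `KnotDistribution`
accepts an explicit `correlation` for users who prefer to fix it.

Negative knot or daily draws are truncated at zero rather than
resampled (≈6 % of DOL1 AA draws); the effect on cumulative moments is
below Monte-Carlo noise at the sizes used. Daily noise is added only
on non-knot days, so the sparse observations are an *exact* subsample
of the daily trajectories — asserted, not assumed.

**Growth generation.** `z36 = z_birth + Δ` with Δ from the ΔZ model
above. Two consequences are documented limitations: the generated
ΔZ is independent of `z_birth`, so the generated 36-week marginal SD is
≈1.0 rather than the published 0.82 (real cohorts show regression to
the mean that the model omits); and the implied below-P10 rate of the
generated cohort differs from one computed directly from the published
Normal(−1.00, 0.82) marginal, which is why the headline below-P10 rate
is simulated from that marginal directly (`CohortSpec.z36_marginal_*`).
The AA-dose practice rate "≥1.5 g/kg/d on DOL1" is not an input
probability: it emerges from the knot distribution
(P(N(1.1, 0.7) ≥ 1.5)·0.93 ≈ 0.26 vs the published 27 %). Weights are
back-transformed through the growth reference, so
`zscore(value_from_z(z)) = z` round-trips by construction. All 36-week
measurements are taken at exactly 252 days PCA. Morbidity flags,
center-level practice heterogeneity, and any coupling between illness
and intake are not emulated — passing tests demonstrate the pipeline's
correctness on cohorts with this covariance structure, not the clinical
truth of any particular effect estimate.

**Determinism.** One `numpy.random.default_rng` (PCG64) drives the
whole cohort; a fixed `CohortSpec.seed` reproduces every file byte.
The acceptance script derives independent streams for its three
simulations from the single `--seed` via `SeedSequence.spawn`.

## Problem sizes and numerical choices

Simulation sizes are chosen for tight Monte-Carlo error at interactive
cost: 10⁶ draws for the below-P10 rate (binomial SE ≈ 0.05 points),
1 000 trajectories for the estimator validation (r² SE ≈ 0.002), 200
replicates of n = 276 for parameter recovery (SE of the mean tertile
coefficient ≈ 0.002). Piecewise-linear equivalence is asserted at
relative 10⁻¹², the residual of summing 14 doubles versus 4 products.
The deficit identity is asserted in its defining form
`deficit == horizon·target − intake` (bit-exact); the re-associated
form `(intake + deficit) == horizon·target` is checked to one unit in
the last place, since IEEE addition does not guarantee the
re-association bit-for-bit.

## Interfaces

The repository-level shape is a statsmodels-style pair for the
inferential core — `DeltaZModel` (construction, screening policy) and
`DeltaZResults` (estimates, partial correlations, `summary()`); the
arithmetic and scoring stages are plain functions over small frozen
dataclasses, and the CLI (`simulate`, `intake`, `comply`, `growth`,
`analyze`, `validate-estimator`, `run`) is a thin wrapper over the
library. The `run` pipeline writes a manifest (config hash, seed,
library versions) and is byte-identical on re-run with a fixed config
and seed; timestamps are deliberately excluded from every output.
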