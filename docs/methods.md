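# Methods

This note documents the models, defaults and design choices behind
`clustercea`: what each stage assumes, what the synthetic trial
generator does and does not emulate, and where genuinely open design
questions were settled.

## Effect estimation under the cluster design

Arm differences are estimated by a linear mixed model on the
participant-level analysis frame:

    y_ij = β0 + β1·arm_j + τ_{township(j)} + γ·y_ij(baseline) + δ1·age_ij + δ2·sex_ij + b_j + ε_ij

with a random intercept `b_j` per village `j` (REML) and township fixed
effects mirroring the stratified randomization. The reported quantity is
β1 (intervention − control) with its model SE and a normal-approximation
95% CI. Analyses are intention-to-treat; participants missing the
outcome wave are excluded from that outcome's model (complete case), and
deaths contribute to QALYs through the death rule rather than being
dropped.

When the random-intercept variance estimate collapses to the boundary or
the REML fit fails — likely with few clusters or near-zero ICC — the
implementation falls back to OLS with the same fixed-effect design and
village-clustered robust SEs, and logs the event. The two estimators
target the same coefficient; with a balanced design their point
estimates are essentially identical, so the fallback changes inference
only through the SE.

`unadjusted_difference` (raw arm means, villages as independent units)
exists as an audit baseline. Whether costs should be covariate-adjusted
is genuinely open in trial-based practice; both paths are implemented
and the adjusted difference is the default ICER input.

## Bootstrap and acceptability curves

Uncertainty combines cost and effect noise by resampling villages with
replacement within township × arm strata (the randomization design's
exchangeable units), re-estimating both adjusted differences per
replication. Inside replications the fixed-effect design is refit by
plain least squares: cluster resampling already carries the
between-village variance, the OLS arm coefficient is the same estimand,
and it keeps 5000 replications near a minute instead of tens of minutes.
An individual-level resampling option is deliberately absent — it would
understate variance under clustering.

The CEAC reports `p(λ) = P(λ·ΔE − ΔC ≥ 0)` over an ascending grid
(default 0 to twice the willingness-to-pay threshold, 101 points). The
ICER 95% CI is the percentile interval of the draw-wise ratio restricted
to draws with positive incremental effect, with that interpretable
fraction reported alongside; ratio percentiles are ill-defined across
quadrants, and the restriction plus disclosure is the transparent
compromise. Quadrant conventions: benefit-positive effects, so NE =
costlier & more effective, SE = dominant, NW = dominated; a zero effect
difference yields an undefined ratio (NaN) with a flag, not an
exception.

## QALYs, death handling, discounting

Utility trajectories are piecewise linear through observed waves;
missing interior waves are linear interpolations between flanking
observations. From the date of death utility is 0; between the last
observation and death the default is a linear decline to 0 (the
alternative last-value-carried-forward step, then drop at death, is
available via `death_transition="locf"`). Survivors are never
extrapolated past their last wave — requesting area beyond it is an
error, not a guess. Annual QALYs use calendar years from baseline with
fractional last years pro-rated by trapezoid.

Discounting applies only to post-trial streams, anchored at the end of
the within-trial year, at 5%/year by default (deterministic sensitivity
range 3–8%): `PV = Σ v_t/(1+r)^t` over whole years.

The EQ-5D-5L conversion is a plain additive tariff: index =
anchor − Σ decrements, with the national value-set coefficients accepted
as a user-supplied table (they are licensed externally). The packaged
`synthetic_value_set` is exactly that — synthetic — with smooth level
decrements scaled so the worst state maps to a configurable floor
(default −0.391).

## Costing

All aggregation is in reference-year (2023) USD. Historical
local-currency amounts are first inflated by a rural consumer price
index, then converted once at the reference-year exchange rate; the
order is chosen for unit coherence and both factors are configuration.
Cost items carry an explicit currency year, and summing mixed years is a
hard error. Medication items are quantity × unit price × adherence with
adherence accepted as a precomputed [0,1] factor (upstream adherence
instruments vary; the multiplicative discount is the common kernel).
Outpatient cost is a flat per-participant-year literature value (45.5
USD within-trial) because trial-linked outpatient records are typically
unavailable. Post-trial inpatient costs are imputed as self-reported
visit counts × within-trial mean episode cost per cause. Program
delivery costs are an itemized ledger amortized over the served
population.

## Synthetic trial generator

The generator emulates the study conditions the analysis assumes: 5
townships × 10 villages × ~26 participants (1299 total), village-level
1:1 allocation stratified by township, baseline SBP ~ N(145.9, 22.4²)
with a village random intercept (ICC 0.05), baseline utility
N(0.80, 0.20²) truncated to [floor, 1], ~2.3% first-year mortality under
a constant hazard (deaths lose their follow-up wave), and 1-year changes

* SBP: control drift −4.3 mmHg, true arm effect −2.8 mmHg, regression to
  the mean 0.2, village-level change SD 2.35 and residual SD 12 — chosen
  so the adjusted effect SE is ≈0.94 mmHg, the precision the published
  interval implies at this design size;
* utility: control drift −0.06, true arm effect +0.06, residual SD 0.18.

Costs: inpatient episodes are zero-inflated gamma by cause (control use
probabilities 0.20/0.12/0.25, means 320/230/200 USD, shape 0.9); the
configured per-person arm difference in inpatient cost (default
−32.4 USD) is induced by scaling intervention-arm use probabilities.
Medication classes use published per-user means with assumed uptake
fractions; intervention uptakes are back-solved so the per-person arm
differences equal the published +2.11/+0.09/+2.99 USD. Intervention
participants carry a flat 50.8 USD program cost. The configured true
total incremental cost is therefore 50.8 + 5.19 − 32.4 = 23.59 USD;
`SimConfig.calibrated()` instead pins it to exactly 23.3 by absorbing
the difference into the inpatient component. Simulated amounts are
emitted directly in reference-year USD (the CPI path is exercised by its
own tests, not the generator).

What the generator does **not** emulate: within-person cost–outcome
correlation, seasonal measurement timing, differential attrition by arm,
item nonresponse, village-level cost clustering, or medication-regimen
detail below class totals. Passing recovery tests therefore shows the
pipeline is unbiased and correctly calibrated under its own assumptions,
not that those assumptions hold in any particular real trial.

A post-trial extension (waves at 5.3 and 5.9 years, cumulative arm
mortality 17.3%/20.4%, utility drift per arm) can be enabled for
longer-horizon analyses; it shares the death and interpolation rules.

## Budget-impact model

Year-1 eligible population = base population × stroke prevalence
(2.58%) × rural share (52.9%); the base defaults to the value that
reproduces the published year-1 count (855,498,161 — the publication
prints only the product). Subsequent years default to a **calibrated**
net annual rate back-solved from the published year-1 and year-5 counts
(≈0.041%/year), because the separately stated rates (8.26% incidence, 1%
growth, 0.16% death) cannot jointly reproduce that trajectory; a
`stated_rates` mode applying them literally is provided as exploratory.

Per-participant component schedules are 5-year configuration vectors,
not constants. The defaults are calibrated assumptions: a standalone
bundle falling 16.93 → 6.68 USD (first-year-only development, training
and supervision; village-doctor visits declining from monthly toward
quarterly) and an integration-incremental bundle (voice messages, system
costs, incremental medications) falling 5.41 → 2.256 USD, back-solved
from the published scenario-B averages and the published coverage split
(7,125,158 of 11,676,010 ≈ 61%). Under scenario B, covered participants
incur only the incremental bundle; uncovered participants the full
bundle. Two monotonicity properties follow by construction and are
asserted in tests: scenario B is never costlier per participant than A,
and later years are never costlier than year 1. Outputs are nominal
(undiscounted) per-year amounts, matching budget-impact convention.

## Numerical choices and degenerate inputs

* Seeds: every stochastic routine takes an explicit integer seed and
  spawns independent `numpy` generator streams for trial structure vs
  cost items, so the same config + seed is byte-identical.
* QALY integration is segment-wise over stored breakpoints, so
  zero-width steps (carried-forward utility dropping at death)
  integrate exactly.
* Degenerate data: zero-variance inputs make every bootstrap draw equal
  the point estimate; a township with a single arm, one village per
  arm, or all-one-arm data raise named validation errors rather than
  silently producing an unidentified fit.
* Rounding: eligible populations round to whole persons at reporting
  points only; projections compound in floating point.

## Replication-ensemble reporting

The headline reproduction (incremental cost per mmHg) is reported as the
ratio of pooled adjusted estimates over an ensemble of independently
seeded calibrated trials (default 2000 trials, ≈2.6M simulated
participants). The pooled ratio converges to the configured
23.3/2.8 ≈ 8.32 USD/mmHg with Monte-Carlo SE ≈ 0.13 at the default size,
whereas any single trial's point ICER has MC noise of roughly ±2 — the
effect-SE of 0.94 mmHg alone implies that much. Reporting the ensemble
ratio is therefore the package's way of separating pipeline bias (what
the check is about) from single-realization sampling noise (which the
bootstrap quantifies, and which the published trial's own single
realization also carries).

## Known limitations

* The mixed model covers only the design used here (one random
  intercept, township fixed effects); no GEE, crossed effects, or
  survival modelling of mortality.
* ICER percentile CIs are not Fieller intervals; with effect
  distributions near zero they should be read alongside the quadrant
  proportions.
* The budget-impact model is deterministic (point estimates only) and
  national-level; no province disaggregation or uncertainty analysis.
* Costs in the generator are independent across participants given arm;
  real cost data often show village-level clustering that would widen
  the cost CI.
* No multiple imputation: complete-case handling matches the primary
  analysis convention but assumes missingness unrelated to outcome
  given covariates.
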