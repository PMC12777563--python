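# Methods

This note records the model, the numerical procedures, and the design
choices made where the published description left the design open.

## Structural and statistical model

Piperacillin disposition is one-compartment with zero-order infusion
input and first-order elimination; all regimens are infusions, so no
separate bolus solution is needed.  Concentration under superposed
infusion events is evaluated in closed form (rise
`(R0/CL)(1 − e^(−kτ))` during an event, exponential decay after), which
is exact and orders of magnitude faster than ODE integration; the closed
form is property-tested against an independent ODE oracle at 1e-6
relative tolerance.

Individual parameters: `CL_i = θ_CL (CrCL_i/99.3)^β exp(η_CL + κ_CL)`,
`V_i = θ_V exp(η_V)` with η between-subject and κ between-occasion
effects.  When clearance changes between occasions, the compartment
amount is propagated exactly across the occasion boundary, so profiles
stay continuous with piecewise-constant elimination.

Defaults are the published estimates (θ_CL 12.0 L/h at the reference
CrCL 99.3 mL/min, θ_V 29.8 L, β 0.64, BSV 36.2/57.3 CV%, BOV 16.4 CV%,
residual a 5.5 mg/L + b 0.20, fu 0.70, assay LLOQ 0.58 mg/L).

Two conventions required a decision:

- **CV% → log-SD.**  Printed variabilities are treated as log-normal
  coefficients of variation and converted by `ω = sqrt(log(1 + CV²))`;
  the alternative reading `ω = CV` differs by < 3% at these magnitudes
  and is available (`cv_conversion="direct"`).
- **Residual model.**  The combined error is the "combined1" form
  `y = f + (a + b f) ε`, the convention of the software family the
  estimates were reported from.  Negative simulated observations are
  retained and flagged BLQ rather than truncated, so the error model
  stays exactly Gaussian.

## Dosing simulation and target attainment

For each regimen and a fixed CrCL, cohorts are drawn (BSV always;
BOV optional, new occasion every 24 h), profiles computed over 48 h, and
PTA is the percentage of subjects whose **unbound** concentration is at
or above the target at **every** evaluation time.  No residual error is
added: attainment is a property of the model concentration, not of a
noisy measurement.

**Evaluation window (key reconstruction).**  The default evaluates on a
dense 0.05 h grid over (0.5 h, 48 h] — excluding only the first 30 min,
the duration of the initial short/loading infusion, since concentrations
start at zero.  This choice was forced by internal evidence: pre-dose
trough evaluation cannot produce the published pattern in which
no-loading-dose extended infusions attain high targets *less* often than
short infusions of the same daily dose (steady-state troughs of an
extended infusion are strictly higher), whereas dense evaluation
reproduces every published panel — the slow 3–4 h first-infusion ramp is
what penalizes extended infusions started without a loading dose.  With
this window and BSV only, all eight reference grid cells recompute
within ~1 pp (one within 4 pp); with BOV added all remain within 5 pp.
Both the trough-only mode (`eval_mode="trough"`) and BOV
(`bov=True`) remain available.

The published grid's "22 g q6h" high-dose panel is ambiguous; it is
implemented as 2 g LD + 5.5 g q6h over 3 h (22 g/day).  It does not
reproduce that panel's printed values and is excluded from default
recommendation queries; none of the reference cells use it.

Other simulation choices: strict `≥` at the threshold (ties have measure
zero under continuous variability); CrCL fixed per cell, not resampled;
within `pta_table` the random effects are drawn once per regimen and
shared across the CrCL grid (common random numbers), which makes the
monotone decrease of PTA in CrCL exact rather than statistical; default
n = 1000 per cell with the seed recorded, 10,000 in the acceptance
recomputation (binomial SE ≤ 0.5 pp).

Recommendations select, among regimens with PTA ≥ 90% at the queried
CrCL and target and toxicity probability (unbound ≥ 160 mg/L throughout)
below a cap, those with the lowest nominal daily dose, listing
continuous infusion first on ties.

## Synthetic cohorts

The generator emulates the source study's design: 44 subjects (21
extended- / 23 short-infusion), 4 g q6h with the first dose always a
30-min infusion, three sampling occasions mapped to treatment days 1, 3
and 5 (configurable), sparse sampling (−10 and 180 min; third occasion
adds 270 min) and an intensive subgroup (10/21 and 14/23 per arm) whose
occasion 2 uses the intensive schedule (EI: −10/180/210/240/270; SI:
−10/30/60/90/180/270 min).  This yields 394 observations per default
cohort.  Covariates match the published cohort: age N(55.4, 10.2²) y,
weight and CrCL log-normal moment-matched to the printed median and
inter-quartile interval (`μ = log median`, `σ = log(q75/q25)/(2·0.6745)`),
47.7% male, albumin N(3.4, 0.4²) g/dL, CrCL clipped to 30–250 mL/min and
jittered across occasions (log-normal, median 1, median relative change
≈ 6.6%).

What the generator does **not** emulate: missed samples and dropout (the
real study recorded 221 of a nominal ~390 samples), assay censoring
mechanics beyond a BLQ flag at 0.58 mg/L, non-protocol dose adjustments,
and any clinical outcomes.  Passing recovery tests therefore show that
the estimator is consistent under the design, not that it would be
unbiased under real-world messiness.

## Estimation

The marginal likelihood integrates the per-subject random effects
(η_CL, η_V, κ per occasion) with a **Laplace approximation** at the
per-subject posterior mode.  Modes are found by a damped, trust-region
Newton iteration vectorized across subjects; gradients and Hessians of
the penalized objective use central finite differences evaluated as one
batched model call per iteration (step 1e-3; inner tolerance 5e-4 on the
gradient, just above the FD noise floor).  Effects whose SD falls below
1e-4 are treated as structurally zero and dropped from the integral.
Fixed effects, covariate exponents, variances and error terms are
optimized by L-BFGS-B on a log-transformed scale (bounds keep SDs in
[1e-3, 3]); starting values come from pooled two-point log-linear
estimates with ω/γ at 30%/15% CV unless the user supplies them.  The
estimator is a consistent maximum-likelihood procedure; it does not
replicate any particular software's stochastic algorithm.

Continuous covariates enter clearance as a power of the value normalized
to the dataset median (CrCL occasion-wise), binary covariates as
`exp(β x)`; `covariate_refs` can pin the normalization (e.g. at
99.3 mL/min) so θ_CL keeps a fixed meaning across datasets.  Stepwise
selection uses ΔOFV ≥ 3.84 forward and ≥ 10.83 backward.

Wald standard errors come from a finite-difference Hessian of −2LL with
a deliberately coarse step (0.02): the objective carries ~1e-5 numerical
noise from the inner modes, which a second difference divides by h².
Non-positive-definite information matrices are projected to the nearest
PD matrix, inflating the affected intervals rather than failing.
Calibration on 20 synthetic 100-subject cohorts generated from the
default truth gave median absolute relative errors of ~4% (θ_CL, at the
fit's own reference) and ~6% (θ_V), with the Wald 95% interval for β
covering the generating value in 19/20 runs.

The Laplace −2LL agrees with a dense tensor Gauss–Hermite quadrature
oracle to < 0.1 on small intensively sampled datasets with moderate
variability; under very sparse designs with the full published
variability the Laplace error grows to ~0.1–0.4 in −2LL — a known
property of the approximation, and one reason stochastic-integration
estimators exist.

BLQ observations (< 0.58 mg/L, including negative draws) are dropped
from the likelihood (M1) but kept, flagged, in datasets.  The pc-VPC
uses **all** observations: its simulations are uncensored, so dropping
low observations on one side would bias the comparison.  Prediction
correction scales each value by (bin median population prediction)/(own
population prediction), bins on time after dose (quantile bins, merged
on ties), and compares observed 5th/50th/95th percentiles with 2.5–97.5%
bands from 500 simulated replicates of the design.

The nonparametric bootstrap resamples subjects with replacement and
refits from the point estimate; non-converged replicates are excluded
and counted.

## Problem sizes used in the test suite

Tests run the acceptance grid cells at n = 10,000 subjects per cell, the
full monotonicity grid at n = 1000, parameter recovery over 20 seeds at
100 subjects each, the pc-VPC at 500 simulations, and bootstrap
mechanics at small replicate counts; these sizes give Monte Carlo error
well inside each assertion's tolerance while keeping the suite fast.

## Known limitations

- One compartment only; no saturable elimination; piperacillin only
  (tazobactam was not measured in the source study).
- Recommendations apply to CrCL ≥ 30 mL/min and the first 48 h of
  empirical therapy; no dose rounding to vial sizes; no renal-impairment
  schedules beyond q8h.
- The Laplace approximation is biased for very sparse designs (above).
- Printed-table reproduction inherits the evaluation-window
  reconstruction described under dosing simulation; the 22 g/day panel
  is not reproduced.
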