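# Methods

## Model

The illness-death model has three states — healthy, diseased, dead — with
irreversible transitions: incidence `i(a)` (healthy → diseased), mortality
`m1(a)` of the diseased and `m0(a)` of the non-diseased. Age-specific
prevalence `p(a, t)` obeys the transport equation

    (∂/∂t + ∂/∂a) p = (1 − p) [ i − p (m1 − m0) ].

The state-specific mortalities are never observed directly; they are
recovered at every evaluation point from all-cause mortality
`m = p·m1 + (1−p)·m0` and the mortality-rate ratio `MRR = m1/m0`:

    m0 = m / (1 + p(MRR − 1)),   m1 = MRR · m0.

Solving the same equation for `i` gives the inversion used on observed
prevalence:

    i = dp/(1−p) + m · p(MRR−1) / (1 + p(MRR−1)).

**Assumptions.** (1) No remission and no migration. (2) `m1` does not depend
on disease duration. (3) No calendar trend: the ten annual cross-sections
are pooled into one cross-section at the study midpoint t = 2013.5, so the
PDE reduces along characteristics to an ODE in age. (4) Diagnosed prevalence
at birth is zero: `p(0) = 0`. (5) The diseased population above age 110 is
ignored (mortality tables close at the 110+ terminal group).

## Parametric curves

- Incidence: Gaussian in age, `i(a) = β₁ exp(−½((a−β₂)/β₃)²)`.
  β₁ (per person-year) is the peak height, β₂ (years) the peak age, β₃
  (years) the width. β₂ is **fixed** during estimation — eight aggregated
  proportions cannot localise the peak — at 87.5 y, the midpoint of the
  85–89 interval where Danish registry data place the hypertension
  incidence maximum; sensitivity refits at 85 and 90 are supported.
- MRR: log-linear in age, `log MRR(a) = γ₁ + (a−30)/70 (γ₂−γ₁)`, anchored
  at ages 30 (γ₁) and 100 (γ₂). Two Gompertz hazards with different
  baselines have exactly log-linear log-ratio, which motivates the form.
  The line extrapolates linearly outside [30, 100]; below 30 the diseased
  population is so small that those values carry almost no weight.

Ages are continuous; parameters are kept at full floating precision.

## Estimation

Observed data: proportions `prev` with denominators `denom` per (sex, year,
age group) on the groups 0–24, 25–34, …, 75–84, 85–109. Years are pooled by
averaging each group's proportions (denominators summed). Sexes are fitted
completely independently.

The default ("trajectory") objective forward-solves the ODE at candidate
(β₁, β₃, γ₁, γ₂), aggregates the solved curve to the groups, and minimises
the sum of squared prevalence residuals (optionally denominator-weighted).
Group aggregation options:

- `midpoint` (default): evaluate the curve at the group's representative
  age, `(lo + hi + 1)/2` for closed groups (25–34 → 30); the open 85–109
  group is represented by **91 y** = 85 + pooled remaining life expectancy
  e(85) ≈ 6 y.
- `weighted`: survival-weighted mean of the curve over the group's ages,
  with stationary-population weights `exp(−∫m)`.

In the noiseless limit the two options give fits whose (β₁, β₃) differ by a
few per cent (≈5% on β₁ at the default truths) — a structural sensitivity of
mapping a continuous curve to eight wide groups, larger for the weakly
identified γ's. The midpoint convention is the default and is what the
synthetic generator uses.

A secondary "derivative" objective implements the direct inversion route:
2nd-order central differences of the pooled group prevalences across the
representative ages are plugged into the inversion formula and matched
against the parametric `i(a)`. Differencing eight values spaced 10 years
apart carries an O(width²) bias — on noiseless data it lands within ~7% of
the trajectory fit's β₁ — and is noise-amplifying, which is why trajectory
matching is the default.

**Optimizer.** Nelder-Mead simplex on (log β₁, log β₃, γ₁, γ₂) (log scale
enforces positivity), from start (0.05, 25, 0.4, 0.0) plus 3 seeded random
restarts; lowest objective wins, ties broken by run order; `xatol = 1e-6`.
Box constraints β₁ ∈ [0,1], β₃ ∈ (1,80), γ ∈ [−3,3] are enforced by a large
finite penalty growing with the violation, so the simplex never sees an
exception; β₁ = 0 (the zero-height curve) is a legitimate degenerate fit and
is reported with a boundary flag rather than an error. Non-convergence is
reported in the result object, never raised.

## Numerics

- Forward solver: classical fixed-step RK4, step 0.05 y on [0, 110]
  (configurable, capped at 0.1 y), rate curves pre-tabulated at half-step
  resolution. Fixed step keeps runs bit-reproducible across platforms.
  Step-halving agreement is ~1e-13; the solution matches a step-1e-4 Euler
  oracle to <1e-5.
- Inversion of a solved/observed curve differentiates with 4th-order central
  differences on uniform grids (round-trip error <1e-5 absolute on ages
  30–95 across random parameter draws).
- Mortality tables are interpolated **log-linearly** between integer ages —
  exact for Gompertz hazards; nearest tabulated calendar year is used (the
  window is one cross-section). Zero rates are floored at 1e-10 before logs.
- Remaining life expectancy `e(a) = ∫ exp(−∫m)` uses a trapezoidal
  cumulative hazard and Simpson's rule at step 0.005 y, truncated at 110
  (documented tail loss; e.g. 1.7e-4 y for a constant hazard 0.1).

## Bootstrap

Individual-level resampling is impossible for aggregated proportions, so
uncertainty is propagated by perturbation: each cell's proportion gets an
independent Gaussian deviation with its binomial standard error
`sqrt(p(1−p)/n)` (truncated to [0,1]), the model is refitted, and parameter
and incidence-table distributions are summarised by the median and the
2.5%/97.5% empirical quantiles (B = 1,000 in production use). Replicate b
draws from an RNG stream keyed by (seed, b): results are independent of
execution order. Replicates are warm-started at the base-data fit with a
single simplex run; non-converged replicates are dropped with a logged
count, and >20% failures abort with an error. Reported incidence rows
(labels 30, 35, …, 95) are evaluated at the interval midpoints label + 2.5 —
the convention under which the row labelled 85 equals the peak height β₁·10⁴
and rows are symmetric about it — with a flag for raw-label evaluation.

## Synthetic data

The generator emulates the aggregated claims-prevalence structure: eight age
groups × two sexes × years 2009–2018, denominators (9.0, 5.0, 5.0, 6.5, 5.5,
4.5, 3.5, 1.0) million per sex and group following the population pyramid at
~35 million insured per sex, truth = the pipeline's own forward model at the
default parameters (male β₁ = 0.0763, β₃ = 25.33680, γ₁ = 0.408,
γ₂ = −0.0171; female β₁ = 0.0635, β₃ = 25.18237, γ₁ = 0.321, γ₂ = −0.0376),
observation = Binomial(denom, p)/denom per cell. Mortality is Gompertz,
calibrated once so that life expectancy at birth is 78 y (men) / 83 y
(women) and e(85) is 5.44 / 6.38 y — giving the pooled e(85) ≈ 6 y that
motivates the top-group representative age 91: male (g0 = −10.707,
g1 = 0.10043), female (g0 = −12.430, g1 = 0.11696).

Not emulated: diagnostic coding behaviour and the two-quarter confirmation
criterion, under-diagnosis, calendar trends, private-insurance selection,
duration-dependent mortality. Passing tests therefore demonstrate that the
pipeline recovers parameters when the data really follow the model at claims
scale — they cannot validate the structural assumptions against real claims
data.

## Test and script sizing

Test runs scale the expensive pieces down: bootstrap behaviour is checked at
B = 100 (intervals at multi-million denominators are already <1% wide
relative), interval coverage over 10 synthetic worlds at B = 25, and the
acceptance script reports bootstrap medians at B = 100. The β₂ sensitivity
mechanism is verified on synthetic data whose true peak is at 87.5: fixing
β₂ at 85/90 shifts the fitted peak row by ~11–12% while rows at ages ≤70
move by <4%, so the qualitative bounds tested are 20% (peak) and 5%
(age 60).

## Known limitations

- Estimates describe **diagnosed** prevalence/incidence; no correction for
  undetected disease.
- The Gaussian incidence and log-linear MRR are structural choices; the
  narrow bootstrap intervals quantify sampling noise *within* the chosen
  model, not model uncertainty.
- β₂ is externally fixed; mis-specifying it by ±2.5 y moves the peak height
  by ~10–15% (see above).
- The derivative objective mode is exposed for completeness but carries a
  coarse-grouping bias and should not be preferred on real data.
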