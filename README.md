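# idminc

Age- and sex-specific **incidence** of a chronic disease estimated from
**aggregated prevalence** and **all-cause mortality** data via the
illness-death model (IDM).

Registry publications often report prevalence of a diagnosis (e.g. arterial
hypertension in German statutory-health-insurance claims, ~70 million
insured) only as proportions by sex and broad age group, with no individual
records and no follow-up. Cohort-style incidence estimation is impossible
with such data. The IDM makes it possible anyway: in a three-state model
(healthy → diseased → dead, healthy → dead, no remission) prevalence `p`,
incidence `i` and the state-specific mortalities `m0`, `m1` are linked by the
transport equation

```
(∂/∂t + ∂/∂a) p = (1 − p) · [ i − p·(m1 − m0) ]
```

Only all-cause mortality `m = p·m1 + (1−p)·m0` and the mortality-rate ratio
`MRR = m1/m0` are needed to close the system. `idminc` parameterises

- the incidence curve as a Gaussian in age,
  `i(a) = β₁·exp(−½((a−β₂)/β₃)²)`, with the peak age β₂ fixed (87.5 y by
  default, the midpoint of the 85–89 interval where external registry data
  place the hypertension incidence maximum), and
- the MRR as log-linear in age,
  `log MRR(a) = γ₁ + (a−30)/70·(γ₂−γ₁)` (γ₁, γ₂ = log MRR at ages 30/100),

then estimates (β₁, β₃, γ₁, γ₂) per sex by nonlinear least squares: solve the
prevalence ODE forward from `p(0)=0`, aggregate to the observed age groups
(0–24, 25–34, …, 75–84, 85–109; the open top group represented by age 91 ≈
85 + remaining life expectancy), and match the observed proportions.
Uncertainty comes from a **perturbation bootstrap**: each replicate re-noises
every observed proportion with its binomial standard error, refits, and the
2.5%/97.5% quantiles over replicates give 95% confidence intervals.

A synthetic-data generator reproduces the structure of the claims dataset
(eight age groups × two sexes × ten years, multi-million denominators,
binomial sampling, Gompertz mortality calibrated to German life expectancy),
so the whole pipeline is testable without any restricted download.

## Worked example

```python
from idminc import IDMIncidenceEstimator, PerturbationBootstrap
from idminc.synthetic import SyntheticConfig, generate_dataset

observed, mortality, _ = generate_dataset(SyntheticConfig(seed=1))
male = observed[observed.sex == "male"]
hazard = mortality.hazard("male", 2013.5)

est = IDMIncidenceEstimator(hazard=hazard, random_state=0).fit(male)
print(f"beta1={est.beta1_:.4f} beta3={est.beta3_:.3f} "
      f"gamma1={est.gamma1_:.3f} gamma2={est.gamma2_:.4f}")

boot = PerturbationBootstrap(hazard=hazard, B=100, seed=0).fit(male)
row85 = list(boot.eval_labels).index(85)
s = boot.summary_
print(f"peak incidence {s.incidence_median[row85]:.2f} per 10,000 py "
      f"(95% CI {s.incidence_lo[row85]:.2f}-{s.incidence_hi[row85]:.2f})")
```

prints

```
beta1=0.0763 beta3=25.339 gamma1=0.398 gamma2=-0.0151
peak incidence 762.59 per 10,000 py (95% CI 761.40-764.00)
```

i.e. the fitted male incidence peaks at ≈763 cases per 10,000 person-years
in the middle of the 85–89 age interval, with a very narrow bootstrap
interval — the generating truth was β₁ = 0.0763/person-year, recovered to
three digits from binomially noised group proportions. Incidence-table rows
are labelled 30, 35, …, 95 and evaluated at the interval midpoints
(label + 2.5), so the row labelled 85 equals the curve's maximum.

The same pipeline runs from the shell:

```bash
idminc simulate --seed 1 --out data/
idminc fit       --prevalence data/prevalence.csv --mortality data/mortality.csv --out results/
idminc bootstrap --prevalence data/prevalence.csv --mortality data/mortality.csv \
                 --replicates 1000 --seed 0 --out results/
idminc report    --summary results/bootstrap_male.json --summary results/bootstrap_female.json \
                 --out results/incidence_table.csv --plot results/incidence.png
```

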