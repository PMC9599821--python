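# medroute

Causal mediation analysis of a binary exposure's effect on conditional
mortality through a binary mediator (diagnostic route), built for
registry-like cancer cohorts. The package decomposes the total causal effect
of comorbidity on death within conditional follow-up windows into natural
direct and indirect effect odds ratios via Monte Carlo g-computation, reports
the proportion mediated on the odds-ratio scale, and ships descriptive
(contingency-table odds ratios, chi-squared tests) and net-survival
(inverse-expected-survival-weighted excess hazard, Kaplan–Meier) companion
layers. A synthetic cohort generator with a fully enumerable generating
process provides exact ground truth for every estimator.

## Layout

| module | contents |
| --- | --- |
| `medroute.synthetic_cohort` | `ScenarioSpec`, `generate_cohort`, exact `true_natural_effects` enumeration oracle, Gompertz life tables |
| `medroute.descriptive` | cross-tabulations, Wald odds ratios, chi-squared tests, per-decade age OR |
| `medroute.net_survival` | `pohar_perme` weighted net survival, `kaplan_meier`, life-table hazard lookup |
| `medroute.mediation` | conditional window outcomes, mediator/outcome logistic models, single stochastic imputation of the missing mediator, g-computation of TCE/NDE/NIE/PM, percentile bootstrap |
| `medroute.io`, `medroute.pipeline`, `medroute.cli` | CSV/YAML I/O with strict validation, end-to-end runner with manifest, `medroute` CLI |

## CLI

```sh
medroute simulate --n 20000 --seed 1 --out cohort.csv --lifetable lt.csv
medroute describe --cohort cohort.csv --out out/
medroute netsurv  --cohort cohort.csv --lifetable lt.csv --by comorbidity --times 12,36,60 --out out/
medroute mediate  --cohort cohort.csv --windows 1,2,3 --bootstrap 1000 --mc-draws 50 --seed 1 --out out/
medroute run      --config run.yaml
```

Cohort CSV header:
`patient_id,age,sex,deprivation,ethnicity,comorbidity,route,follow_up_months,dead,diagnosis_year`
with `sex` in {male, female}, `ethnicity` in {white, other}, `route` in
{elective, emergency} or empty (missing), `deprivation` 1–5 (1 = least
deprived), age 45–99. Life tables are CSV with columns `age,sex,year,rate`
(expected deaths per person-year).

## Methodology notes

* Conditional windows are (0,12], (12,36] and (36,60] months; each window's
  analysis restricts to patients alive at the window start and refits all
  models.
* The mediator model is logistic M ~ A + C; the outcome model is logistic
  Y ~ A + M + A×M + C with C = (age per decade, sex, deprivation contrasts,
  ethnicity). Missing mediator values are singly stochastically imputed from
  a logistic model on (A, C, Y) inside the g-computation (and re-drawn inside
  every bootstrap replicate).
* Natural effect odds ratios are marginal over the at-risk confounder
  distribution; `nde_or_closed_form`/`nie_or_closed_form` expose the
  conditional closed-form contrasts for verification. The decomposition
  TCE = NDE × NIE holds as an algebraic identity of the estimator.
* Proportion mediated: PM = OR_NDE(OR_NIE − 1)/(OR_NDE·OR_NIE − 1).
* Net survival uses monthly discretization (deaths at month-end, integer-year
  ageing) in product-limit form, so a zero life table reproduces the
  Kaplan–Meier estimator exactly.
* All randomness flows from one master seed through
  `numpy.random.SeedSequence.spawn` in a fixed order.

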