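# survcompare

Right-censored survival analysis with two competing modelling tracks —
parametric **censored Weibull accelerated-failure-time (AFT) regression**
and a nonparametric **random survival forest (RSF)** — plus the comparison
framework (prediction error rate, Harrell C-index, most-predictive
variables) needed to adjudicate between them on the same cohort.

The toolkit is aimed at biostatisticians and clinical researchers modelling
durations such as a patient's length of stay in a surgical ward: each
record is a positive time t (hours), an event indicator δ (1 = observed,
0 = right-censored) and a mix of numeric and categorical covariates.

## Models

**Weibull AFT.** Yᵢ = log Tᵢ = xᵢ'β + σνᵢ with νᵢ standard Gumbel-minimum,
so Tᵢ is Weibull with shape γ = 1/σ and characteristic life exp(xᵢ'β).
Parameters are estimated by right-censored maximum likelihood

L(θ) ∝ ∏ᵢ f(yᵢ; θ)^{δᵢ} S(yᵢ; θ)^{1−δᵢ},  S(y) = exp(−exp((y − x'β)/σ)),

with Wald and likelihood-ratio inference, Cox–Snell / martingale / deviance
residual diagnostics, case-deletion influence analysis, and the
median-time-ratio interpretation exp(β̂ⱼ) of each coefficient.

**Random survival forest.** Bagged binary survival trees: each tree grows
on a bootstrap sample, splitting nodes on the covariate/threshold pair that
maximizes the absolute standardized log-rank statistic |LR(x, c)| among
mtry randomly drawn candidates, until nodes are small (< 2·nodesize) or
death-free. Terminal nodes carry Nelson–Aalen cumulative hazards;
out-of-bag (OOB) ensemble hazards yield per-record mortality scores, the
OOB error 1 − C, and random-daughter variable importance (VIMP).

Shared primitives — Kaplan–Meier, Nelson–Aalen, the multi-group log-rank
test and the Harrell C-index with survival-forest tie handling — live in
`survcompare.survival_core`. A seeded synthetic-cohort generator
(`survcompare.simulate`) draws Weibull AFT cohorts with configurable
covariates and calibrated uniform censoring, including a default
configuration emulating a 145-patient cardiac-surgery cohort.

## Worked example

Fit both tracks to a simulated cardiac-like cohort (300 patients, true
effects: fast-track −0.26, coronary +0.56 on log-hours, σ = 0.22, 25%
censoring):

```python
import survcompare as sc

config = sc.SimulationConfig(
    n=300,
    coefficients={"intercept": 1.59, "protocol[fast-track]": -0.26,
                  "patient[coronary]": 0.56},
    sigma=0.22,
    covariate_spec={
        "age": sc.NumericCovariate("uniform", 1.0, 80.0),
        "protocol": sc.CategoricalCovariate(("conventional", "fast-track"), (0.39, 0.61)),
        "patient": sc.CategoricalCovariate(("congenital", "coronary"), (0.48, 0.52)),
    },
    censoring=0.25,
    seed=20230313,
)
data = sc.simulate_cohort(config)

fit = sc.fit_weibull_aft(data, covariates=["protocol", "patient"])
print(fit.summary().round(4))

report = sc.compare_models(data, sc.ForestConfig(n_trees=500, seed=1))
print(report.to_frame().to_string(index=False))
```

which prints

```
                      estimate  std_error  p_value
intercept               1.5586     0.0254      0.0
protocol[fast-track]   -0.2385     0.0278      0.0
patient[coronary]       0.5562     0.0270      0.0
tau                    -1.5918     0.0508      0.0

             model  error_rate  c_index most_predictive_variables
    RSF (training)    0.253054 0.746946    patient, protocol, age
     RSF (testing)    0.206374 0.793626    patient, protocol, age
Weibull regression    0.231810 0.768190         protocol, patient
```

The AFT fit recovers the generating coefficients within two standard
errors. `exp(−0.2385) ≈ 0.79` says the fast-track median stay is about 79%
of the conventional one (any quantile scales by the same factor); the
forest rows report OOB error on the training partition and all-tree
ensemble error on a 30% stratified holdout, and both tracks agree on the
two real effects while the forest also ranks the noise covariate `age`
(with a small positive VIMP) — rankings below the top effects are noisy at
this cohort size.

The same workflow is available from the shell:

```sh
survcompare simulate --seed 3 --out cohort.csv --schema-out schema.yaml
survcompare fit-weibull --data cohort.csv --schema schema.yaml \
    --covariates protocol,patient --out fit.json
survcompare fit-rsf --data cohort.csv --schema schema.yaml \
    --ntree 1000 --nodesize 10 --seed 1 --out forest.json
survcompare compare --data cohort.csv --schema schema.yaml \
    --seed 1 --out table.csv --format csv
```

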