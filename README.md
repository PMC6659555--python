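# smokesurvey

Simulation and design-based weighting toolkit for stratified multistage
face-to-face smoker surveys.

National tobacco-policy cohort studies recruit ~1000 adult smokers per
country through a stratified multistage protocol: geographic strata (region
× urbanization level), ~100 area clusters allocated proportionally to adult
population with a two-cluster floor per stratum, a random route selecting
every 5th dwelling, a household screener counting adult smokers, selection
of at most one male and one female smoker per household by the next-birthday
rule, and a quota of 10 completed interviews per cluster.  `smokesurvey`
implements the computational machinery of such a survey so that each piece
can be validated on synthetic populations where the truth is known:

- **synthetic populations** — strata → clusters → households → adults with
  sex, age group, smoker status, behavioural attributes and fieldwork
  propensities (`smokesurvey.population`);
- **fieldwork simulation** — the full recruitment protocol with disposition
  accounting (`smokesurvey.sampling`);
- **outcome rates** — the standard contact / cooperation / response-rate
  ladder derived from disposition counts (`smokesurvey.rates`), including a
  packaged six-country disposition table from a 2016 European smoker survey
  wave (`smokesurvey.datasets`);
- **survey weights** — the four-step chain (`smokesurvey.weights`):
  initial weight *w₁ᵢ = kᵢ* (the reciprocal of the within-household
  selection probability 1/kᵢ, with kᵢ the number of same-sex smokers);
  design weight *w₂ᵢ ∝ w₁ᵢ* scaled within each stratum *h* so that
  Σᵢ∈h w₂ᵢ ∝ Nₕ (adult population); calibration of *w₂* to external
  benchmark smoker counts over stratum, sex and age group by raking
  (iterative proportional fitting) or joint-cell post-stratification; and
  rescaling to mean 1 per country;
- **Rao–Wu rescaled bootstrap** — replicate weights
  *wᵢ(b) = wᵢ · (nₕ/(nₕ−1)) · m_c(b)*, where each replicate redraws
  nₕ−1 of a stratum's nₕ sampled clusters with replacement and m_c(b)
  is the draw count of respondent *i*'s cluster; variances, percentile and
  normal confidence intervals from the replicate distribution
  (`smokesurvey.bootstrap`);
- **estimation** — Hájek (weighted-mean) proportions, a calibration margin
  audit, and a reproducible end-to-end pipeline with manifest
  (`smokesurvey.estimation`, `smokesurvey.pipeline`, CLI `smokesurvey`).

## Worked example

Outcome rates from the packaged German disposition column:

```python
from smokesurvey import load_wave1_dispositions, compute_rates

rates = compute_rates(load_wave1_dispositions()["Germany"]).rounded()
```

prints, field by field:

```
eligibility_rate                   0.358
estimated_eligible_households      3694.0
household_contact_rate             0.8
household_cooperation_rate         0.983
household_response_rate            0.294
individual_cooperation_rate        0.834
individual_response_rate           0.704
```

i.e. 35.8% of screened households contained an eligible smoker; applying
that rate to all 10 325 attempted addresses gives an estimated 3694
eligible households, of which 1085 allowed selection — a household response
rate of 0.294.  (The estimated eligible count uses the *unrounded*
eligibility rate: 0.358 × 10325 would give 3696, not the correct 3694.)

A full simulated survey — 40 000-adult synthetic country, 40 clusters,
quota 10, four-step weights, B = 500 bootstrap replicates:

```python
from smokesurvey.population import generate_population
from smokesurvey.sampling import run_fieldwork
from smokesurvey.studies import study_population_config, study_design, weights_for_sample
from smokesurvey.bootstrap import rao_wu_replicates
from smokesurvey.estimation import estimate_proportion

pop = generate_population(study_population_config(), seed=42)
sample = run_fieldwork(pop, study_design(), seed=7)
ws = weights_for_sample(sample, pop)           # initial -> design -> raked -> mean-1
rw = rao_wu_replicates(ws, sample, B=500, seed=11,
                       benchmark=pop.true_margins(), strata=pop.strata)
y = sample.respondents["daily_smoker"].to_numpy(float)
print(estimate_proportion(y, ws, rw, label="daily smoking among smokers").summary())
```

```
daily smoking among smokers: 0.7877 (SE 0.0223, percentile 95% CI [0.7428, 0.8272], B=500)
```

against a true population value of 0.8209 for this seed — inside the
interval, about 1.5 standard errors from the point estimate, as expected
for a single cluster-sample draw of ~400 respondents.

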