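# mentholsim

A discrete-time microsimulation of cardiovascular disease (CVD) among
adult cigarette smokers, built to project the 20-year health and
economic impact of a menthol cigarette ban in a large US city and to
examine how that impact is distributed across sex and race/ethnicity.

It is aimed at health-policy modelers and epidemiologists who want a
reproducible, fully configurable pipeline: synthetic cohort in, paired
policy scenarios out, with every parameter exposed in one YAML file.

## The model

A cohort of `n` adult smokers is generated with joint demographics
(sex × race/ethnicity strata, banded ages) and CVD risk factors (BMI,
SBP, LDL-C, HDL-C, diabetes). Each person is a menthol or non-menthol
smoker with probability taken from a sex × race/ethnicity prevalence
matrix (default cells are an independence scaling of the published 2018
NYC margins: 25.6 / 83.8 / 59.8% by race/ethnicity, 44.1 / 59.3% by
sex, 49% overall).

Each simulated year, every living person passes through, in order:
non-CVD death (sex/age life table), CVD death, first myocardial
infarction (MI), first stroke, cost accrual, ageing. Annual event
probabilities follow a logistic risk equation per outcome:

    P(event) = exp(α + Σ_k β_k x_k) / (1 + exp(α + Σ_k β_k x_k))

with covariates age, sex, race/ethnicity, BMI, SBP, LDL-C, HDL-C,
diabetes and smoking status. Healthcare costs accrue as age-banded
background costs plus event and post-event costs, discounted at 3%/yr
to 2018 dollars.

**The menthol ban** is a one-time shock at baseline: each current
menthol smoker quits with probability 21.2% (the cessation response
observed after Ontario's 2017 menthol ban); the rest switch to
non-menthol cigarettes at identical risk. Ban and status-quo runs share
the same cohort and the same uniform draws per (person, year,
transition) — common random numbers — so paired differences isolate the
policy effect: a 0% quit scenario reproduces the status quo bitwise,
and averted-case estimates are low-variance.

The shipped risk coefficients, life table, risk-factor distributions
and cost parameters are **synthetic plausible values** (the original
cohort fits and expenditure figures are not public), calibrated only to
coarse magnitudes. Absolute projections depend on them; the pairing
identities, dose-response and subgroup orderings do not.

## Worked example

```python
from mentholsim import load_config, run_replicates, summarize
from mentholsim.reporting import rounded_headlines

cfg = load_config()                       # packaged default config
results = run_replicates(
    cfg.population, cfg.scenarios, cfg.models,
    n=10_000, horizon=20, base_seed=1, replicates=50,
)
for k, v in rounded_headlines(summarize(results, population_size=cfg.population_size)).items():
    print(f"{k}: {v}")
```

prints

```
mi_per_million_status_quo: 66292
stroke_per_million_status_quo: 54590
mi_per_million_ban: 62712
stroke_per_million_ban: 52340
averted_mi_per_million: 3580
averted_stroke_per_million: 2250
pct_reduction_mi: 5.4
pct_reduction_stroke: 4.1
per_person_saving: 179
total_saving_billion: 0.16
```

Read: without the ban the model projects ~66,000 MI and ~55,000 stroke
cases per million adult smokers over 20 years; the ban averts ~3,600 MI
and ~2,300 stroke cases per million (a 5.4% and 4.1% reduction) and
saves ~$179 per person in discounted healthcare costs (~$0.16B across
880,000 smokers). With the default prevalence matrix the reductions are
largest for non-Latino Black women and smallest for non-Latino White
men — the disparity-narrowing pattern the subgroup report
(`mentholsim.subgroup_report`) quantifies cell by cell.

The same experiment from the shell, including the quit-proportion sweep
and subgroup table as CSVs plus a reproducibility manifest:

```bash
mentholsim --seed 1 --replicates 200 --outdir out/
```

## Layout

| module | contents |
| --- | --- |
| `mentholsim.population` | `PersonState`, `PopulationSpec`, `Cohort`, `generate_population`, menthol assignment, CSV round-trip |
| `mentholsim.risk` | logistic `RiskCoefficients`, `annual_event_probability`, sex/age `LifeTable` |
| `mentholsim.policy` | `PolicyScenario`, `apply_policy` (the quit shock) |
| `mentholsim.costs` | `CostParameters`, `discount`, `annual_cost` |
| `mentholsim.engine` | `run_year`, `run_scenario`, `run_replicates`, CRN draw streams |
| `mentholsim.reporting` | per-million scaling, averted/reduction/saving arithmetic, subgroup and sweep tables, percentile CIs |
| `mentholsim.config` / `mentholsim.cli` | YAML validation with dotted-path errors; the `mentholsim` command |

See `docs/methods.md` for modelling assumptions, parameter provenance
and known limitations.
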