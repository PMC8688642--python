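# Methods

## Model structure

The package is a closed-cohort, discrete-time (annual cycle)
microsimulation. A cohort of adult cigarette smokers is generated at
baseline (2018); no one enters later, and the cohort is followed for a
fixed horizon (default 20 years). Within a year each living person is
advanced through a fixed transition order:

1. non-CVD death (life-table lookup by sex and age band),
2. CVD death (logistic risk equation),
3. first incident MI (logistic; at most one per person over the run),
4. first incident stroke (logistic; likewise at most one),
5. cost accrual (start-of-year age, discounted to baseline),
6. ageing by one year.

The order is a convention; the model has no within-year competing-risk
refinement. A person can have both an MI and a stroke (same or
different years); each outcome is counted once per person. Persons who
die in a year accrue no events or costs in that year, and the dead
never accrue anything afterwards. Prior events do not alter later
event probabilities unless the user adds the `had_mi` / `had_stroke`
covariates to a coefficient set (default betas: absent). Risk factors
other than age are frozen over the horizon — the policy question is
the effect of smoking status, and letting diet/adiposity drift would
confound it.

## Annual event probabilities

Each outcome (MI, stroke, CVD death) has its own logistic model:
`P = expit(alpha + sum_k beta_k x_k)` with covariates drawn from age,
sex, race/ethnicity indicators, BMI, SBP, LDL-C, HDL-C, diabetes, and
smoking-status indicators. `scipy.special.expit` keeps the computation
stable for |eta| well past 700 (no overflow; probabilities saturate to
0/1 only at float64 limits).

Smoking is coded as `current_smoker` (menthol and non-menthol carry
identical risk — the ban's benefit operates entirely through quitting)
and `former_smoker` (default beta 0, i.e. quitting immediately confers
baseline risk; a cessation lag can be modelled by giving
`former_smoker` a positive beta).

The shipped coefficient values are **synthetic**: the pooled-cohort
fits the design is patterned on are not published. They were chosen
once for epidemiological plausibility (positive age/SBP/LDL/diabetes
gradients, negative HDL, male excess for MI) and calibrated to two
coarse magnitudes only: 20-year cumulative MI incidence among the
default smoker cohort in the 4–8% band, and stroke slightly below MI.
The `current_smoker` betas (0.70 for MI, 0.46 for stroke) mean
quitting roughly halves MI odds and cuts stroke odds by ~37%, which is
what places the cohort-level reductions near 5% and 4% when ~10% of the
cohort (49% menthol × 21.2%) quits.

## Non-CVD mortality

A synthetic sex-specific life table, age-banded on [18, 100) and
monotone in age, with male rates above female. Ages at or past 100 use
the last band. It is deliberately simple: background mortality only
needs to thin the cohort realistically; it is identical across
scenarios except through the (small) CVD-death difference.

## Synthetic population

The generator emulates the joint structure of a city's adult smokers
with configurable pieces:

- **Strata.** Six (sex × race/ethnicity) cells; default weights are
  derived from published weighted menthol-smoker counts divided by the
  published cell prevalences, then normalised (male 60.4%, female
  39.6%; non-Latino White 40.6%, non-Latino Black 30.1%, Latino
  29.2%), combined under independence.
- **Age.** Uniform within four bands (18–25, 25–45, 45–65, 65–85) with
  band weights recovered the same way from the published age rows.
- **Risk factors.** Independent parametric marginals (normal or
  lognormal, config-chosen), with an optional linear age trend used by
  default only for SBP (+0.45 mmHg per year from age 45). Values are
  clamped to plausibility bounds (BMI 12–80, SBP 70–260, LDL-C 20–400,
  HDL-C 10–150). This is a stand-in for the unavailable survey joint
  distribution, not a fit to it: real risk factors are mutually
  correlated, so cohort-level risk heterogeneity is understated.
- **Menthol use.** A full sex × race/ethnicity probability matrix.
  Only the margins are published, so default cells are the
  independence scaling `cell = race_margin × sex_margin / overall`
  (overall 0.49), clamped to [0, 1] — the non-Latino Black × female
  cell clamps at 1.0. The matrix is data, not code; replace it when a
  jointly tabulated source exists.

One consequence worth knowing: the three modelled race/ethnicity
groups account for ~721k of the 880k smokers behind the published 49%
overall menthol share, and the excluded groups smoke less menthol, so
the synthetic cohort's overall menthol share is ~54%. Cell-level
prevalences still match their configured values exactly (in
expectation); only the overall average shifts.

What passing tests therefore show: marginal recovery, pairing
identities, orderings and sensitivity directions. What they do not
show: fidelity of absolute event counts or costs to any real
population.

## Policy operator

The ban is a one-time shock at `start_year_index` (default 0): each
current menthol smoker quits with probability `quit_proportion`
(default 0.212); non-quitters are relabelled non-menthol smokers
(switching), which leaves their risk unchanged under the default
coding. No relapse, no initiation effects. A zero quit proportion is a
strict no-op, so the null policy is bitwise-identical to the status
quo.

## Randomness and pairing

All uniforms come from counter-style numpy `SeedSequence` streams
keyed `(stream, seed, replicate, year, transition)`, with `person_id`
as the offset inside each stream. Scenarios run with the same seed and
replicate therefore consume identical uniforms per (person, year,
transition) — common random numbers — and differ only through the
probabilities compared against them. Quit draws use a separate stream
with one uniform per person, shared across scenarios, so quitter sets
are nested in the quit proportion and the averted-cases curve is a
paired comparison at every point. Row order never affects outcomes
(draws are keyed by person id, not position).

Pairing makes ban event tallies dominate status-quo tallies replicate
by replicate in practice. Dominance is not a theorem: a quitter spared
a CVD death can live to draw an event their status-quo twin never
faced. At the default scale that channel is well under one event per
replicate against ~30 averted MIs, so the suite asserts dominance
empirically at the full design size.

## Costs

Undiscounted annual cost = background(age band) + one-time costs for
this year's incident events + post-event annual costs for conditions
established in earlier years. Event years therefore include background
plus the event cost; post-event annual costs are increments on top of
background. Discounting divides by `(1 + r)^t` with year 0
undiscounted; `r` defaults to 0.03 and is accepted in [0, 0.10]
(CLI sensitivity range 0–0.06). Background bands partition [18, 100);
ages past 100 reuse the last band. Dollar values are synthetic
placeholders of realistic magnitude (mean discounted 20-year cost per
person ≈ $41k under defaults); the per-person saving they imply
(~$180) is an order of magnitude below the published figure, which is
expected — savings are driven by the unpublished event/post-event cost
parameters and by how background costs are treated after CVD onset.

## Aggregation

Per-million rates are `count × 1e6 / n`. Replicate uncertainty is
summarised by percentile intervals (2.5/97.5) over independent
replicates (default 200), which contain Monte-Carlo error only — no
parameter uncertainty. Averted cases, percent reductions and savings
are computed on replicate means; subgroup percent reductions are
within-cell (cell averted over cell status-quo burden). Display
rounding (integers for per-million counts and dollars, two decimals
for billions, one for percents) is applied only in `rounded_headlines`
and the CLI outputs; internal arithmetic is never rounded.

## Problem sizes

The default experimental design is 10,000 persons × 20 years × 200
paired replicates; the vectorised engine runs a scenario-replicate in
~50 ms, so the full design takes well under a minute and the test
suite exercises it directly. Sweeps default to one tenth of the
replicate count of the main comparison; the acceptance script uses 50
replicates for the 50%-quit point.

## Known limitations

- Only CVD outcomes; no lung cancer/COPD, initiation, secondhand
  exposure, or smoking-intensity dimension.
- Independent risk-factor marginals understate between-person risk
  correlation.
- SES is absent from the risk equations, so no education/income
  subgroup outputs.
- Synthetic coefficients/costs: absolute projections are
  order-of-magnitude only; relative and ordering results are the
  robust outputs.
- Percentile CIs reflect simulation noise, not parameter uncertainty.
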