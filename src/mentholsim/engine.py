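"""Annual-cycle microsimulation with paired (common-random-number) runs.

Each simulated year advances every living person through a fixed
transition order: non-CVD death, CVD death, incident MI (first only),
incident stroke (first only), cost accrual, then ageing by one year.
Every potential transition consumes one uniform draw compared against
its probability (inverse-CDF rule).

Randomness contract
-------------------
All uniforms are indexed by ``(seed, replicate, year, transition,
person_id)`` and are therefore identical across policy scenarios run
with the same seed and replicate.  Scenarios differ only through the
probabilities those shared uniforms are compared against, so paired
scenario differences isolate the policy effect (common random numbers).
The policy quit draw uses its own stream, independent of all event
streams, and row order never affects any person's outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .costs import CostParameters, accrue_costs
from .errors import ConfigError
from .policy import PolicyScenario, apply_policy
from .population import (
    Cohort,
    PopulationSpec,
    STRATA,
    RACE_CODES,
    SEX_CODES,
    generate_population,
)
from .risk import (
    LifeTable,
    RiskCoefficients,
    event_probabilities,
    non_cvd_death_probabilities,
)

# stream tags (first entry of the seed-sequence entropy)
_EVENTS, _QUIT, _GEN = 0, 1, 2

# transition codes within the event stream
T_NON_CVD_DEATH, T_CVD_DEATH, T_MI, T_STROKE = 0, 1, 2, 3

DEATH_NONE, DEATH_NON_CVD, DEATH_CVD = -1, 0, 1


class DrawStream:
    """Deterministic uniform streams for one ``(seed, replicate)`` pair."""

    def __init__(self, seed: int, replicate_id: int = 0):
        self.seed = int(seed)
        self.replicate_id = int(replicate_id)

    def uniforms(self, year_index: int, transition: int, n: int) -> np.ndarray:
        ss = np.random.SeedSequence(
            [_EVENTS, self.seed, self.replicate_id, int(year_index), int(transition)]
        )
        return np.random.default_rng(ss).random(n)

    def quit_uniforms(self, n: int) -> np.ndarray:
        ss = np.random.SeedSequence([_QUIT, self.seed, self.replicate_id])
        return np.random.default_rng(ss).random(n)

    def generation_entropy(self) -> list[int]:
        return [_GEN, self.seed, self.replicate_id]


@dataclass
class ModelSuite:
    """All parameter blocks the annual cycle needs."""

    coefficients: dict[str, RiskCoefficients]
    life_table: LifeTable
    costs: CostParameters

    def issues(self) -> list[str]:
        out = []
        for outcome in ("mi", "stroke", "cvd_death"):
            if outcome not in self.coefficients:
                out.append(f"coefficients.{outcome}: missing")
            else:
                out.extend(self.coefficients[outcome].issues())
        out.extend(self.life_table.issues())
        out.extend(self.costs.issues())
        return out

    def validate(self) -> "ModelSuite":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self


@dataclass
class SubgroupTally:
    n: int = 0
    mi: int = 0
    stroke: int = 0
    cvd_deaths: int = 0
    non_cvd_deaths: int = 0
    cost: float = 0.0


@dataclass
class ScenarioResult:
    """Cumulative tallies for one scenario in one replicate."""

    scenario: str
    replicate_id: int
    n_simulated: int
    horizon_years: int
    mi: int
    stroke: int
    cvd_deaths: int
    non_cvd_deaths: int
    cost: float
    subgroups: dict[tuple[str, str], SubgroupTally] = field(default_factory=dict)

    @property
    def deaths(self) -> int:
        return self.cvd_deaths + self.non_cvd_deaths

    def check_consistency(self) -> None:
        for name in ("n", "mi", "stroke", "cvd_deaths", "non_cvd_deaths"):
            attr = "n_simulated" if name == "n" else name
            total = sum(getattr(t, name) for t in self.subgroups.values())
            if total != getattr(self, attr):
                raise AssertionError(f"subgroup {name} tallies do not sum to overall")
        cost_total = sum(t.cost for t in self.subgroups.values())
        if abs(cost_total - self.cost) > 1e-6 * max(1.0, abs(self.cost)):
            raise AssertionError("subgroup costs do not sum to overall cost")


def run_year(cohort: Cohort, models: ModelSuite, year_index: int, stream: DrawStream) -> Cohort:
    """Advance the cohort one year in place (and return it).

    Uniform draws are indexed by ``person_id``, so permuting rows
    permutes outcomes identically.
    """
    n_ids = int(cohort.person_id.max()) + 1 if len(cohort) else 0
    ids = cohort.person_id

    alive = cohort.alive

    u = stream.uniforms(year_index, T_NON_CVD_DEATH, n_ids)[ids]
    q_nc = non_cvd_death_probabilities(cohort, models.life_table)
    die_nc = alive & (u < q_nc)

    alive1 = alive & ~die_nc
    u = stream.uniforms(year_index, T_CVD_DEATH, n_ids)[ids]
    p_cvd = event_probabilities(cohort, models.coefficients["cvd_death"])
    die_cvd = alive1 & (u < p_cvd)

    alive2 = alive1 & ~die_cvd
    u = stream.uniforms(year_index, T_MI, n_ids)[ids]
    p_mi = event_probabilities(cohort, models.coefficients["mi"])
    mi_new = alive2 & ~cohort.had_mi & (u < p_mi)

    u = stream.uniforms(year_index, T_STROKE, n_ids)[ids]
    p_st = event_probabilities(cohort, models.coefficients["stroke"])
    stroke_new = alive2 & ~cohort.had_stroke & (u < p_st)

    # costs use start-of-year age and prior-condition flags
    accrue_costs(cohort, alive2, mi_new, stroke_new, models.costs, year_index)

    cohort.had_mi |= mi_new
    cohort.had_stroke |= stroke_new
    cohort.death_cause[die_nc] = DEATH_NON_CVD
    cohort.death_cause[die_cvd] = DEATH_CVD
    cohort.alive = alive2
    cohort.age = np.where(alive2, cohort.age + 1.0, cohort.age)
    return cohort


def _tally(cohort: Cohort, scenario: str, replicate_id: int, horizon: int) -> ScenarioResult:
    subgroups: dict[tuple[str, str], SubgroupTally] = {}
    for sex, race in STRATA:
        m = (cohort.sex == SEX_CODES[sex]) & (cohort.race == RACE_CODES[race])
        subgroups[(sex, race)] = SubgroupTally(
            n=int(m.sum()),
            mi=int(cohort.had_mi[m].sum()),
            stroke=int(cohort.had_stroke[m].sum()),
            cvd_deaths=int((cohort.death_cause[m] == DEATH_CVD).sum()),
            non_cvd_deaths=int((cohort.death_cause[m] == DEATH_NON_CVD).sum()),
            cost=float(cohort.discounted_cost[m].sum()),
        )
    res = ScenarioResult(
        scenario=scenario,
        replicate_id=replicate_id,
        n_simulated=len(cohort),
        horizon_years=horizon,
        mi=int(cohort.had_mi.sum()),
        stroke=int(cohort.had_stroke.sum()),
        cvd_deaths=int((cohort.death_cause == DEATH_CVD).sum()),
        non_cvd_deaths=int((cohort.death_cause == DEATH_NON_CVD).sum()),
        cost=float(cohort.discounted_cost.sum()),
        subgroups=subgroups,
    )
    res.check_consistency()
    return res


def run_scenario(
    spec: PopulationSpec,
    scenario: PolicyScenario,
    models: ModelSuite,
    n: int = 10_000,
    horizon: int = 20,
    seed: int = 0,
    replicate_id: int = 0,
    return_cohort: bool = False,
):
    """Simulate one scenario for one replicate.

    The cohort is generated from ``(spec, seed, replicate_id)`` and the
    policy applied at ``scenario.start_year_index`` before that year's
    event draws.  Fully reproducible from the arguments.
    """
    issues = spec.issues() + models.issues() + scenario.issues()
    if issues:
        raise ConfigError(issues)
    if horizon < 0:
        raise ConfigError(["horizon: must be >= 0"])

    stream = DrawStream(seed, replicate_id)
    cohort = generate_population(spec, n, seed=stream.generation_entropy())

    for year in range(horizon):
        if year == scenario.start_year_index:
            cohort = apply_policy(
                cohort, scenario, stream.quit_uniforms(n)[cohort.person_id]
            )
        run_year(cohort, models, year, stream)
        dead = int((~cohort.alive).sum())
        assert int(cohort.alive.sum()) + dead == n, "person conservation violated"

    result = _tally(cohort, scenario.name, replicate_id, horizon)
    if return_cohort:
        return result, cohort
    return result


def run_replicates(
    spec: PopulationSpec,
    scenarios: list[PolicyScenario],
    models: ModelSuite,
    n: int = 10_000,
    horizon: int = 20,
    base_seed: int = 0,
    replicates: int = 200,
    progress=None,
) -> list[ScenarioResult]:
    """Independent replicates; within a replicate all scenarios share
    the cohort and all event/quit uniform streams (CRN pairing)."""
    if replicates < 1:
        raise ConfigError(["replicates: must be >= 1"])
    out: list[ScenarioResult] = []
    for r in range(replicates):
        for scenario in scenarios:
            out.append(
                run_scenario(
                    spec, scenario, models,
                    n=n, horizon=horizon, seed=base_seed, replicate_id=r,
                )
            )
        if progress is not None:
            progress(r)
    return out
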