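"""Annual cycle, scenario runs, replicates, and CRN pairing."""

import dataclasses
import math

import numpy as np
import pytest

from mentholsim.engine import (
    DEATH_CVD,
    DrawStream,
    run_replicates,
    run_scenario,
    run_year,
)
from mentholsim.errors import ConfigError
from mentholsim.policy import PolicyScenario
from mentholsim.population import generate_population
from mentholsim.reporting import split_by_scenario
from mentholsim.risk import RiskCoefficients


def logit(p):
    return math.log(p / (1 - p))


def test_null_dynamics_changes_only_age_and_cost(spec, null_models):
    coh = generate_population(spec, 1_000, seed=3)
    before = coh.copy()
    run_year(coh, null_models, 0, DrawStream(1))
    assert np.all(coh.age == before.age + 1.0)
    assert np.all(coh.discounted_cost > 0)
    for name in ("person_id", "sex", "race", "bmi", "sbp", "ldl_c", "hdl_c",
                 "diabetes", "smoking", "alive", "had_mi", "had_stroke"):
        assert np.array_equal(getattr(coh, name), getattr(before, name)), name


def test_certain_cvd_death_kills_everyone_with_no_events(spec, null_models):
    models = dataclasses.replace(
        null_models,
        coefficients={
            **null_models.coefficients,
            "cvd_death": RiskCoefficients("cvd_death", alpha=700.0, betas={}),
        },
    )
    coh = generate_population(spec, 500, seed=4)
    run_year(coh, models, 0, DrawStream(1))
    assert not coh.alive.any()
    assert np.all(coh.death_cause == DEATH_CVD)
    assert not coh.had_mi.any() and not coh.had_stroke.any()
    # the dead accrued no cost and did not age
    assert np.all(coh.discounted_cost == 0.0)


def test_forced_mi_rate_recovers_binomial_count(spec, null_models):
    p = 0.01
    models = dataclasses.replace(
        null_models,
        coefficients={
            **null_models.coefficients,
            "mi": RiskCoefficients("mi", alpha=logit(p), betas={}),
        },
    )
    n = 100_000
    coh = generate_population(spec, n, seed=5)
    run_year(coh, models, 0, DrawStream(2))
    count = int(coh.had_mi.sum())
    sd = math.sqrt(n * p * (1 - p))
    assert abs(count - n * p) <= 3 * sd


def test_each_person_counted_once_per_outcome(spec, models, status_quo):
    result, cohort = run_scenario(
        spec, status_quo, models, n=2_000, horizon=20, seed=6, return_cohort=True
    )
    assert result.mi == int(cohort.had_mi.sum())
    assert result.mi + int((~cohort.had_mi).sum()) == result.n_simulated
    assert result.stroke + int((~cohort.had_stroke).sum()) == result.n_simulated


def test_conservation_alive_plus_deaths(spec, models, status_quo):
    result, cohort = run_scenario(
        spec, models=models, scenario=status_quo, n=2_000, horizon=20, seed=7,
        return_cohort=True,
    )
    assert int(cohort.alive.sum()) + result.deaths == result.n_simulated


def test_horizon_zero_yields_nothing(spec, models, status_quo):
    r = run_scenario(spec, status_quo, models, n=200, horizon=0, seed=1)
    assert (r.mi, r.stroke, r.deaths, r.cost) == (0, 0, 0, 0.0)


def test_run_scenario_reproducible(spec, models, ban):
    a = run_scenario(spec, ban, models, n=1_000, horizon=10, seed=9, replicate_id=3)
    b = run_scenario(spec, ban, models, n=1_000, horizon=10, seed=9, replicate_id=3)
    assert a == b


def test_null_policy_is_bitwise_identical_to_status_quo(spec, models, status_quo):
    """CRN identity: a ban that nobody obeys is exactly the status quo."""
    null_ban = PolicyScenario("ban_nobody_quits", quit_proportion=0.0)
    a = run_scenario(spec, status_quo, models, n=2_000, horizon=10, seed=11)
    b = run_scenario(spec, null_ban, models, n=2_000, horizon=10, seed=11)
    assert dataclasses.replace(a, scenario="x") == dataclasses.replace(b, scenario="x")


def test_row_order_does_not_affect_outcomes(spec, models):
    """Draws are keyed by person_id, so permuting the cohort permutes
    the outcome vector identically."""
    from mentholsim.engine import ModelSuite  # noqa: F401  (doc import)
    coh = generate_population(spec, 500, seed=13)
    perm = np.random.default_rng(0).permutation(len(coh))
    shuffled = coh.copy()
    for name in shuffled.__slots__:
        setattr(shuffled, name, getattr(coh, name)[perm].copy())
    run_year(coh, models, 0, DrawStream(5))
    run_year(shuffled, models, 0, DrawStream(5))
    order = np.argsort(shuffled.person_id)
    for name in ("alive", "had_mi", "had_stroke", "discounted_cost", "age"):
        assert np.array_equal(getattr(shuffled, name)[order], getattr(coh, name)), name


def test_replicates_deterministic_and_sized(spec, models, scenarios):
    a = run_replicates(spec, scenarios, models, n=300, horizon=5, base_seed=21, replicates=2)
    b = run_replicates(spec, scenarios, models, n=300, horizon=5, base_seed=21, replicates=2)
    assert a == b
    assert len(a) == 4  # R x scenarios
    one = run_replicates(spec, scenarios, models, n=300, horizon=5, base_seed=21, replicates=1)
    assert len(one) == len(scenarios)


def test_replicate_mean_stable_across_base_seeds(spec, models, status_quo):
    """Monte-Carlo stability: the replicate mean MI rate moves by no
    more than sampling noise when the base seed changes (3 SDs of the
    difference, the same convention as the binomial checks)."""
    R, n = 100, 2_000
    means, ses = [], []
    for seed in (101, 202):
        res = run_replicates(spec, [status_quo], models, n=n, horizon=20,
                             base_seed=seed, replicates=R)
        rates = np.array([r.mi * 1e6 / r.n_simulated for r in res])
        means.append(rates.mean())
        ses.append(rates.std(ddof=1) / math.sqrt(R))
    assert abs(means[0] - means[1]) <= 3 * math.hypot(ses[0], ses[1])


def test_ban_never_exceeds_status_quo_tallies(spec, models, scenarios):
    """CRN dominance at desk scale (the acceptance suite re-checks this
    at the full experimental size)."""
    res = run_replicates(spec, scenarios, models, n=2_000, horizon=20,
                         base_seed=31, replicates=10)
    by = split_by_scenario(res)
    for sq, bn in zip(by["status_quo"], by["menthol_ban"]):
        assert bn.mi <= sq.mi
        assert bn.stroke <= sq.stroke


def test_config_errors_surface_before_any_year_runs(spec, models, status_quo):
    bad_spec = spec.with_menthol_cell("male", "latino", 2.0)
    with pytest.raises(ConfigError, match=r"menthol_prevalence\.male\.latino"):
        run_scenario(bad_spec, status_quo, models, n=100, horizon=5, seed=1)
    with pytest.raises(ConfigError, match="replicates"):
        run_replicates(spec, [status_quo], models, n=10, horizon=1,
                       base_seed=1, replicates=0)
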