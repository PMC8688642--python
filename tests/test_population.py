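"""Synthetic cohort generator: determinism, marginals, invariants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mentholsim.errors import ConfigError, DomainError
from mentholsim.population import (
    AgeBand,
    Cohort,
    PopulationSpec,
    RISK_FACTOR_BOUNDS,
    RiskFactorSpec,
    SEXES,
    RACE_ETHNICITIES,
    STRATA,
    assign_menthol_status,
    generate_population,
)


def test_same_seed_bitwise_identical_cohort(spec):
    a = generate_population(spec, 2_000, seed=11)
    b = generate_population(spec, 2_000, seed=11)
    assert a.equals(b)
    c = generate_population(spec, 2_000, seed=12)
    assert not a.equals(c)


def test_generated_cohort_is_baseline_smokers(spec):
    coh = generate_population(spec, 5_000, seed=3)
    assert len(coh) == 5_000
    assert coh.alive.all()
    assert not coh.had_mi.any() and not coh.had_stroke.any()
    assert np.all(coh.discounted_cost == 0.0)
    # cohort contains only current smokers at baseline
    assert np.isin(coh.smoking, (0, 1)).all()
    assert np.all(coh.age >= 18)
    for name, (lo, hi) in RISK_FACTOR_BOUNDS.items():
        x = getattr(coh, name)
        assert np.all((x >= lo) & (x <= hi))


def test_degenerate_stratum_weight_routes_everyone(spec):
    weights = {c: 0.0 for c in STRATA}
    weights[("female", "nl_black")] = 1.0
    one = dataclasses.replace(spec, strata_weights=weights)
    coh = one.validate() and generate_population(one, 100, seed=7)
    assert np.all(coh.sex == 1) and np.all(coh.race == 1)


def test_stratum_fractions_within_three_binomial_sd(spec):
    n = 50_000
    coh = generate_population(spec, n, seed=3)
    for k, cell in enumerate(STRATA):
        p = spec.strata_weights[cell]
        got = int(((coh.sex == (0 if cell[0] == "male" else 1))
                   & (coh.race == RACE_ETHNICITIES.index(cell[1]))).sum())
        sd = math.sqrt(n * p * (1 - p))
        assert abs(got - n * p) <= 3 * sd, cell


def test_configured_marginals_recovered(spec):
    """Menthol and diabetes prevalence per cell within 3 binomial SDs."""
    n = 50_000
    coh = generate_population(spec, n, seed=5)
    for cell in STRATA:
        mask = (coh.sex == SEXES.index(cell[0])) & (
            coh.race == RACE_ETHNICITIES.index(cell[1])
        )
        m = int(mask.sum())
        for mapping, got in (
            (spec.menthol_prevalence, int((coh.smoking[mask] == 0).sum())),
            (spec.diabetes_prevalence, int(coh.diabetes[mask].sum())),
        ):
            p = mapping[cell]
            sd = math.sqrt(m * p * (1 - p))
            assert abs(got - m * p) <= max(3 * sd, 1e-9), (cell, p)


@pytest.mark.parametrize("p,expected", [(1.0, "current_menthol"), (0.0, "current_nonmenthol")])
def test_assign_menthol_boundaries(p, expected):
    prev = {(s, r): p for s in SEXES for r in RACE_ETHNICITIES}
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert assign_menthol_status("female", "latino", prev, rng) == expected


def test_assign_menthol_matches_cell_probability(spec):
    # male x nl_black default cell: independence-scaled from the
    # published 83.8% (race) and 44.1% (sex) margins
    p = spec.menthol_prevalence[("male", "nl_black")]
    rng = np.random.default_rng(42)
    n = 20_000
    hits = sum(
        assign_menthol_status("male", "nl_black", spec.menthol_prevalence, rng)
        == "current_menthol"
        for _ in range(n)
    )
    sd = math.sqrt(n * p * (1 - p))
    assert abs(hits - n * p) <= 3 * sd


def test_assign_menthol_missing_cell_is_config_error():
    with pytest.raises(ConfigError, match="missing cell"):
        assign_menthol_status("female", "nl_black", {}, np.random.default_rng(0))


def test_default_menthol_margins_match_published_values(spec):
    """The shipped joint matrix is consistent with the published
    margins by construction (cell = race x sex / overall, clamped)."""
    for (sex, race), v in spec.menthol_prevalence.items():
        race_p = {"nl_white": 0.256, "nl_black": 0.838, "latino": 0.598}[race]
        sex_p = {"male": 0.441, "female": 0.593}[sex]
        assert v == pytest.approx(min(1.0, race_p * sex_p / 0.49), abs=5e-7)


def test_invalid_spec_errors_name_offending_field(spec):
    bad = spec.with_menthol_cell("female", "nl_black", 1.5)
    with pytest.raises(ConfigError, match=r"menthol_prevalence\.female\.nl_black"):
        bad.validate()
    weights = dict(spec.strata_weights)
    weights[("male", "nl_white")] += 0.01
    with pytest.raises(ConfigError, match="strata_weights"):
        dataclasses.replace(spec, strata_weights=weights).validate()


def test_n_below_one_rejected(spec):
    with pytest.raises(DomainError):
        generate_population(spec, 0, seed=1)


def test_cohort_csv_round_trip(tmp_path, spec):
    coh = generate_population(spec, 500, seed=9)
    path = tmp_path / "cohort.csv"
    coh.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == (
        "person_id,age,sex,race_ethnicity,bmi,sbp,ldl_c,hdl_c,diabetes,"
        "smoking_status,alive,had_mi,had_stroke,discounted_cost"
    )
    back = Cohort.from_csv(path)
    assert coh.equals(back)


# -- property test over random specs --------------------------------

def _random_spec(draw):
    raw = [draw(st.floats(0.01, 1.0)) for _ in STRATA]
    total = math.fsum(raw)
    weights = {c: v / total for c, v in zip(STRATA, raw)}
    probs = lambda: {c: draw(st.floats(0.0, 1.0)) for c in STRATA}
    n_bands = draw(st.integers(1, 3))
    edges = [18.0]
    for _ in range(n_bands):
        edges.append(edges[-1] + draw(st.floats(2.0, 25.0)))
    braw = [draw(st.floats(0.05, 1.0)) for _ in range(n_bands)]
    bt = math.fsum(braw)
    bands = [
        AgeBand(edges[i], edges[i + 1], braw[i] / bt) for i in range(n_bands)
    ]
    factors = {}
    for name, (lo, hi) in RISK_FACTOR_BOUNDS.items():
        factors[name] = RiskFactorSpec(
            family=draw(st.sampled_from(["normal", "lognormal"])),
            mean=draw(st.floats(lo + 1, min(hi, lo + 150))),
            sd=draw(st.floats(0.5, 25.0)),
            lo=lo,
            hi=hi,
            age_slope=draw(st.floats(-0.5, 0.5)),
        )
    return PopulationSpec(
        strata_weights=weights,
        age_bands=bands,
        risk_factors=factors,
        diabetes_prevalence=probs(),
        menthol_prevalence=probs(),
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data(), seed=st.integers(0, 2**31 - 1))
def test_any_valid_spec_generates_in_range_people(data, seed):
    spec = _random_spec(data.draw)
    spec.validate()
    coh = generate_population(spec, 200, seed=seed)
    assert np.all(coh.age >= 18)
    for name, (lo, hi) in RISK_FACTOR_BOUNDS.items():
        x = getattr(coh, name)
        assert np.all((x >= lo) & (x <= hi))
        assert np.all(x > 0)
    assert np.isin(coh.smoking, (0, 1)).all()
    assert coh.alive.all()
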