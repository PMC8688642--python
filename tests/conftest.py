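import dataclasses

import pytest

from mentholsim import load_config
from mentholsim.policy import PolicyScenario


@pytest.fixture(scope="session")
def cfg():
    """The shipped default configuration, fully validated."""
    return load_config()


@pytest.fixture(scope="session")
def spec(cfg):
    return cfg.population


@pytest.fixture(scope="session")
def models(cfg):
    return cfg.models


@pytest.fixture(scope="session")
def scenarios(cfg):
    return cfg.scenarios


@pytest.fixture(scope="session")
def status_quo(cfg):
    return cfg.scenario("status_quo")


@pytest.fixture(scope="session")
def ban(cfg):
    return cfg.scenario("menthol_ban")


@pytest.fixture()
def null_models(models):
    """Model suite with all transition probabilities driven to ~0.

    Intercepts of -700 saturate the logistic to the float64 underflow
    region (< 1e-300), and the life table is all zeros, so no deaths or
    events can fire.
    """
    coeffs = {
        k: dataclasses.replace(v, alpha=-700.0, betas={})
        for k, v in models.coefficients.items()
    }
    life = dataclasses.replace(
        models.life_table,
        bands={s: [(18.0, 100.0, 0.0)] for s in ("male", "female")},
    )
    return dataclasses.replace(models, coefficients=coeffs, life_table=life)


def make_scenario(q, name=None, start=0):
    return PolicyScenario(
        name=name or f"ban_q{q:g}", quit_proportion=q, start_year_index=start
    )
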