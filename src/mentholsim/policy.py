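"""The menthol-ban intervention operator.

Under the ban, a configured proportion of current menthol smokers quit
(becoming former smokers); the remainder switch to non-menthol
cigarettes, which carry identical risk under the default coefficient
coding.  Non-menthol and former smokers are untouched.  The default
quit proportion of 21.2% reflects the observed cessation response to
the 2017 Ontario menthol ban.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .population import CURRENT_MENTHOL, CURRENT_NONMENTHOL, FORMER, Cohort

DEFAULT_QUIT_PROPORTION = 0.212


@dataclass(frozen=True)
class PolicyScenario:
    """A named intervention applied once at ``start_year_index``."""

    name: str
    quit_proportion: float = DEFAULT_QUIT_PROPORTION
    start_year_index: int = 0

    def issues(self, prefix: str = "scenario") -> list[str]:
        out = []
        if not (0.0 <= self.quit_proportion <= 1.0):
            out.append(
                f"{prefix}.{self.name}.quit_proportion: value "
                f"{self.quit_proportion} outside [0, 1]"
            )
        if self.start_year_index < 0:
            out.append(f"{prefix}.{self.name}.start_year_index: negative")
        return out

    def validate(self) -> "PolicyScenario":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self


STATUS_QUO = PolicyScenario(name="status_quo", quit_proportion=0.0)


def apply_policy(cohort: Cohort, scenario: PolicyScenario, rng) -> Cohort:
    """Return a copy of ``cohort`` with the scenario's quit shock applied.

    Each current menthol smoker independently quits (becomes ``former``)
    with probability ``quit_proportion``; menthol smokers who do not
    quit are relabelled ``current_nonmenthol`` (switching).  Everyone
    else is returned field-for-field unchanged.  A zero quit proportion
    is a true no-op.

    ``rng`` is either a numpy ``Generator`` or a pre-drawn uniform array
    of length ``len(cohort)`` (one draw per person, aligned on row
    order).  Passing the same uniforms across scenarios makes quitter
    sets nested in ``quit_proportion``, which pairs scenario runs for
    variance reduction.
    """
    scenario.validate()
    out = cohort.copy()
    q = scenario.quit_proportion
    if q == 0.0:
        return out
    if isinstance(rng, np.ndarray):
        u = rng
        if u.shape != (len(cohort),):
            raise ConfigError(
                [f"apply_policy: uniform array has shape {u.shape}, want ({len(cohort)},)"]
            )
    else:
        u = rng.random(len(cohort))
    menthol = out.smoking == CURRENT_MENTHOL
    quit = menthol & (u < q)
    out.smoking[quit] = FORMER
    out.smoking[menthol & ~quit] = CURRENT_NONMENTHOL
    return out
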