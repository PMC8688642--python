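"""Exception types shared across the package."""

from __future__ import annotations


class ConfigError(ValueError):
    """A configuration value violates its invariants.

    Carries a list of human-readable issues, each prefixed with a
    dotted path locating the offending key (e.g.
    ``population.menthol_prevalence.female.nl_black``).
    """

    def __init__(self, issues: list[str] | str):
        if isinstance(issues, str):
            issues = [issues]
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


class DomainError(ValueError):
    """An argument is outside the domain an operation is defined on."""


class ComputationError(ValueError):
    """A required input for a computation is missing or non-finite."""
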