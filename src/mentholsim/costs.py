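"""Healthcare cost accrual and discounting (2018 US dollars).

Each living person accrues an age-banded annual background cost; an
incident MI or stroke adds a one-time event cost in the year it occurs,
and previously established conditions add an annual post-event cost on
top of background.  All amounts are discounted to the base year at a
configurable annual rate (3% default) with end-of-year granularity:
year 0 is undiscounted, year t divides by (1 + r)^t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError
from .population import Cohort, PersonState


@dataclass
class CostParameters:
    background_costs: Sequence[tuple[float, float, float]]  # (lo, hi, annual USD)
    mi_event_cost: float
    stroke_event_cost: float
    post_mi_annual_cost: float = 0.0
    post_stroke_annual_cost: float = 0.0
    discount_rate: float = 0.03
    base_year_index: int = 0

    def issues(self, prefix: str = "costs") -> list[str]:
        out = []
        rows = sorted(self.background_costs, key=lambda r: r[0])
        if not rows:
            out.append(f"{prefix}.background: empty")
        else:
            if rows[0][0] != 18:
                out.append(f"{prefix}.background: first band must start at 18")
            if rows[-1][1] != 100:
                out.append(f"{prefix}.background: last band must end at 100")
            for i, (lo, hi, c) in enumerate(rows):
                if not lo < hi:
                    out.append(f"{prefix}.background[{i}]: lo must be < hi")
                if c < 0:
                    out.append(f"{prefix}.background[{i}].cost: negative")
                if i and rows[i - 1][1] != lo:
                    out.append(f"{prefix}.background[{i}]: gap or overlap at age {lo}")
        for name in ("mi_event_cost", "stroke_event_cost",
                     "post_mi_annual_cost", "post_stroke_annual_cost"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                out.append(f"{prefix}.{name}: must be a finite non-negative dollar amount")
        if not (0.0 <= self.discount_rate <= 0.10):
            out.append(f"{prefix}.discount_rate: value {self.discount_rate} outside [0, 0.10]")
        return out

    def validate(self) -> "CostParameters":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        rows = sorted(self.background_costs, key=lambda r: r[0])
        return (
            np.array([r[0] for r in rows], dtype=float),
            np.array([r[2] for r in rows], dtype=float),
        )


def discount(amount: float, year_index: int, rate: float) -> float:
    """Present value at the base year: ``amount / (1 + rate)^year_index``."""
    if year_index < 0:
        raise DomainError(f"year_index must be >= 0, got {year_index}")
    return amount / (1.0 + rate) ** year_index


def background_cost(age: float, params: CostParameters) -> float:
    """Annual background cost for the band covering ``age``.

    Ages at or above the last band's upper edge use the last band (the
    closed cohort ages past 100 late in long horizons); ages below the
    first band are a configuration error.
    """
    los, costs = params._arrays()
    if age < los[0]:
        raise ConfigError([f"costs.background: age {age} below first band"])
    idx = int(np.searchsorted(los, age, side="right")) - 1
    return float(costs[min(idx, len(costs) - 1)])


def background_costs(cohort: Cohort, params: CostParameters) -> np.ndarray:
    los, costs = params._arrays()
    if np.any(cohort.age < los[0]):
        raise ConfigError(["costs.background: cohort contains ages below first band"])
    idx = np.searchsorted(los, cohort.age, side="right") - 1
    return costs[np.clip(idx, 0, len(costs) - 1)]


def annual_cost(
    person: PersonState,
    events_this_year: set[str],
    params: CostParameters,
    year_index: int,
) -> float:
    """Accrue one year of (discounted) cost onto ``person``.

    Undiscounted cost = background(age) + one-time costs for this
    year's incident events + post-event annual costs for conditions
    established in *earlier* years (``person.had_mi`` / ``had_stroke``
    flags, which the caller updates after costing).  The person's
    ``discounted_cost`` increases by exactly the returned amount.
    """
    und = background_cost(person.age, params)
    if "mi" in events_this_year:
        und += params.mi_event_cost
    if "stroke" in events_this_year:
        und += params.stroke_event_cost
    if person.had_mi:
        und += params.post_mi_annual_cost
    if person.had_stroke:
        und += params.post_stroke_annual_cost
    d = discount(und, year_index, params.discount_rate)
    person.discounted_cost += d
    return d


def accrue_costs(
    cohort: Cohort,
    accrue_mask: np.ndarray,
    mi_new: np.ndarray,
    stroke_new: np.ndarray,
    params: CostParameters,
    year_index: int,
) -> None:
    """Vectorised cost accrual used by the simulation engine.

    ``cohort.had_mi``/``had_stroke`` must still hold *prior* conditions
    when this is called (this year's incident events arrive via
    ``mi_new``/``stroke_new``).
    """
    und = background_costs(cohort, params)
    und = und + mi_new * params.mi_event_cost
    und = und + stroke_new * params.stroke_event_cost
    und = und + cohort.had_mi * params.post_mi_annual_cost
    und = und + cohort.had_stroke * params.post_stroke_annual_cost
    factor = 1.0 / (1.0 + params.discount_rate) ** year_index
    cohort.discounted_cost[accrue_mask] += und[accrue_mask] * factor
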