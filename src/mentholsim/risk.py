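"""Annual transition probabilities: CVD events and background mortality.

The annual probability of an incident myocardial infarction, stroke or
CVD death is a logistic function of the person's current covariates,

    P(event in the next year) = expit(alpha + sum_k beta_k * x_k),

with one coefficient set per outcome.  Non-CVD mortality comes from a
sex-specific, age-banded life table.  Both parameter blocks are pure
configuration; the coefficients shipped with the package are plausible
synthetic values, not a published cohort fit (see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import ComputationError, ConfigError, DomainError
from .population import (
    CURRENT_MENTHOL,
    CURRENT_NONMENTHOL,
    FORMER,
    Cohort,
    PersonState,
    RACE_CODES,
    SEX_CODES,
)

OUTCOMES = ("mi", "stroke", "cvd_death")

# Covariates computable from a person's state.  Each entry maps a
# coefficient name to (vectorised extractor over a Cohort, scalar
# extractor from a PersonState).
_COVARIATES = {
    "age": (lambda c: c.age, lambda p: p.age),
    "bmi": (lambda c: c.bmi, lambda p: p.bmi),
    "sbp": (lambda c: c.sbp, lambda p: p.sbp),
    "ldl_c": (lambda c: c.ldl_c, lambda p: p.ldl_c),
    "hdl_c": (lambda c: c.hdl_c, lambda p: p.hdl_c),
    "diabetes": (
        lambda c: c.diabetes.astype(np.float64),
        lambda p: float(p.diabetes),
    ),
    "male": (
        lambda c: (c.sex == SEX_CODES["male"]).astype(np.float64),
        lambda p: float(p.sex == "male"),
    ),
    "female": (
        lambda c: (c.sex == SEX_CODES["female"]).astype(np.float64),
        lambda p: float(p.sex == "female"),
    ),
    "nl_white": (
        lambda c: (c.race == RACE_CODES["nl_white"]).astype(np.float64),
        lambda p: float(p.race_ethnicity == "nl_white"),
    ),
    "nl_black": (
        lambda c: (c.race == RACE_CODES["nl_black"]).astype(np.float64),
        lambda p: float(p.race_ethnicity == "nl_black"),
    ),
    "latino": (
        lambda c: (c.race == RACE_CODES["latino"]).astype(np.float64),
        lambda p: float(p.race_ethnicity == "latino"),
    ),
    "current_smoker": (
        lambda c: np.isin(c.smoking, (CURRENT_MENTHOL, CURRENT_NONMENTHOL)).astype(np.float64),
        lambda p: float(p.smoking_status in ("current_menthol", "current_nonmenthol")),
    ),
    "former_smoker": (
        lambda c: (c.smoking == FORMER).astype(np.float64),
        lambda p: float(p.smoking_status == "former"),
    ),
    "had_mi": (
        lambda c: c.had_mi.astype(np.float64),
        lambda p: float(p.had_mi),
    ),
    "had_stroke": (
        lambda c: c.had_stroke.astype(np.float64),
        lambda p: float(p.had_stroke),
    ),
}

KNOWN_COVARIATES = tuple(_COVARIATES)


@dataclass
class RiskCoefficients:
    """Log-odds intercept and per-covariate weights for one outcome."""

    outcome: str
    alpha: float
    betas: dict[str, float]

    def issues(self, prefix: str = "coefficients") -> list[str]:
        out = []
        loc = f"{prefix}.{self.outcome}"
        if self.outcome not in OUTCOMES:
            out.append(f"{loc}: unknown outcome (expected one of {OUTCOMES})")
        if not math.isfinite(self.alpha):
            out.append(f"{loc}.alpha: non-finite")
        for name, beta in self.betas.items():
            if name not in _COVARIATES:
                out.append(
                    f"{loc}.betas.{name}: unknown covariate "
                    f"(known: {', '.join(KNOWN_COVARIATES)})"
                )
            if not math.isfinite(beta):
                out.append(f"{loc}.betas.{name}: non-finite")
        return out

    def validate(self) -> "RiskCoefficients":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self


def annual_event_probability(person: PersonState, coeffs: RiskCoefficients) -> float:
    """Annual probability of ``coeffs.outcome`` for one person.

    Computed as ``expit(eta)``, numerically stable for |eta| up to and
    beyond 700 (never overflows; saturates to 0/1 in float64 only in
    the far tails).
    """
    eta = coeffs.alpha
    for name, beta in coeffs.betas.items():
        if name not in _COVARIATES:
            raise ConfigError([f"coefficients.{coeffs.outcome}.betas.{name}: unknown covariate"])
        x = _COVARIATES[name][1](person)
        if not math.isfinite(x):
            raise ComputationError(
                f"covariate {name} is non-finite for person {person.person_id}"
            )
        eta += beta * x
    return float(expit(eta))


def event_probabilities(cohort: Cohort, coeffs: RiskCoefficients) -> np.ndarray:
    """Vectorised :func:`annual_event_probability` over a cohort."""
    eta = np.full(len(cohort), coeffs.alpha, dtype=np.float64)
    for name, beta in coeffs.betas.items():
        if name not in _COVARIATES:
            raise ConfigError([f"coefficients.{coeffs.outcome}.betas.{name}: unknown covariate"])
        x = _COVARIATES[name][0](cohort)
        if not np.all(np.isfinite(x)):
            raise ComputationError(f"covariate {name} contains non-finite values")
        eta += beta * x
    return expit(eta)


@dataclass
class LifeTable:
    """Annual non-CVD death probability by age band and sex.

    ``bands[sex]`` is a list of ``(lo, hi, q)`` with the bands
    partitioning [18, 100) for each sex; queries at age >= 100 use the
    last band.
    """

    bands: dict[str, Sequence[tuple[float, float, float]]]

    def issues(self, prefix: str = "life_table") -> list[str]:
        out = []
        for sex in ("male", "female"):
            rows = sorted(self.bands.get(sex, ()), key=lambda r: r[0])
            loc = f"{prefix}.{sex}"
            if not rows:
                out.append(f"{loc}: missing")
                continue
            if rows[0][0] != 18:
                out.append(f"{loc}: first band must start at 18")
            if rows[-1][1] != 100:
                out.append(f"{loc}: last band must end at 100")
            for i, (lo, hi, q) in enumerate(rows):
                if not lo < hi:
                    out.append(f"{loc}[{i}]: lo must be < hi")
                if not (0.0 <= q <= 1.0):
                    out.append(f"{loc}[{i}].q: value {q} outside [0, 1]")
                if i and rows[i - 1][1] != lo:
                    out.append(f"{loc}[{i}]: gap or overlap at age {lo}")
        return out

    def validate(self) -> "LifeTable":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self

    def _arrays(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        rows = sorted(self.bands[sex], key=lambda r: r[0])
        los = np.array([r[0] for r in rows], dtype=float)
        qs = np.array([r[2] for r in rows], dtype=float)
        return los, qs


def non_cvd_death_probability(age: float, sex: str, table: LifeTable) -> float:
    """Annual probability of death from non-CVD causes."""
    if age < 18:
        raise DomainError(f"age {age} below 18")
    los, qs = table._arrays(sex)
    idx = int(np.searchsorted(los, age, side="right")) - 1
    idx = min(max(idx, 0), len(qs) - 1)
    return float(qs[idx])


def non_cvd_death_probabilities(cohort: Cohort, table: LifeTable) -> np.ndarray:
    """Vectorised life-table lookup for a whole cohort."""
    if np.any(cohort.age < 18):
        raise DomainError("cohort contains ages below 18")
    out = np.empty(len(cohort), dtype=np.float64)
    for sex, code in SEX_CODES.items():
        mask = cohort.sex == code
        if not mask.any():
            continue
        los, qs = table._arrays(sex)
        idx = np.searchsorted(los, cohort.age[mask], side="right") - 1
        out[mask] = qs[np.clip(idx, 0, len(qs) - 1)]
    return out
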