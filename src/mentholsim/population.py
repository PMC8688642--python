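"""Synthetic cohort of adult cigarette smokers.

The simulated population emulates the joint demographic and
cardiovascular risk-factor structure of adult smokers in a large US
city: stratum shares over sex and race/ethnicity, a banded age
distribution, independent parametric marginals for BMI, systolic blood
pressure, LDL-C and HDL-C (optionally with a linear age trend),
stratum-specific diabetes prevalence, and a sex-by-race/ethnicity
menthol-cigarette prevalence matrix.  All generative parameters live in
:class:`PopulationSpec`; nothing is hard-coded, so every marginal can be
overridden from the config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

SEXES = ("male", "female")
RACE_ETHNICITIES = ("nl_white", "nl_black", "latino")
SMOKING_STATUSES = ("current_menthol", "current_nonmenthol", "former")

SEX_CODES = {s: i for i, s in enumerate(SEXES)}
RACE_CODES = {r: i for i, r in enumerate(RACE_ETHNICITIES)}
SMOKING_CODES = {s: i for i, s in enumerate(SMOKING_STATUSES)}

CURRENT_MENTHOL, CURRENT_NONMENTHOL, FORMER = 0, 1, 2

#: hard plausibility bounds the generator clamps each risk factor to
RISK_FACTOR_BOUNDS = {
    "bmi": (12.0, 80.0),
    "sbp": (70.0, 260.0),
    "ldl_c": (20.0, 400.0),
    "hdl_c": (10.0, 150.0),
}

STRATA = tuple((s, r) for s in SEXES for r in RACE_ETHNICITIES)


@dataclass
class PersonState:
    """One simulated smoker.

    Costs are cumulative and already discounted to the base year
    (2018 dollars).  Event flags are monotone: once ``had_mi`` or
    ``had_stroke`` is set it never reverts, and dead persons accrue no
    further events or costs.
    """

    person_id: int
    age: float
    sex: str
    race_ethnicity: str
    bmi: float
    sbp: float
    ldl_c: float
    hdl_c: float
    diabetes: bool
    smoking_status: str
    alive: bool = True
    had_mi: bool = False
    had_stroke: bool = False
    discounted_cost: float = 0.0


PERSON_FIELDS = tuple(f.name for f in fields(PersonState))


@dataclass(frozen=True)
class RiskFactorSpec:
    """Parametric marginal for one continuous risk factor.

    ``mean`` and ``sd`` are on the natural (measurement) scale for both
    families; for ``lognormal`` they are converted to the underlying
    normal parameters via the usual moment match.  ``age_slope`` adds a
    deterministic linear age trend ``slope * (age - age_ref)`` before
    clamping to ``[lo, hi]``.
    """

    family: str  # "normal" | "lognormal"
    mean: float
    sd: float
    lo: float
    hi: float
    age_slope: float = 0.0
    age_ref: float = 45.0

    def issues(self, name: str) -> list[str]:
        out = []
        if self.family not in ("normal", "lognormal"):
            out.append(f"{name}.family: unknown family {self.family!r}")
        if not (self.mean > 0 and math.isfinite(self.mean)):
            out.append(f"{name}.mean: must be positive and finite")
        if not (self.sd > 0 and math.isfinite(self.sd)):
            out.append(f"{name}.sd: must be positive and finite")
        if not self.lo < self.hi:
            out.append(f"{name}: lo must be < hi")
        return out

    def sample(self, rng: np.random.Generator, ages: np.ndarray) -> np.ndarray:
        n = ages.shape[0]
        if self.family == "normal":
            x = rng.normal(self.mean, self.sd, size=n)
        else:  # lognormal, moment-matched on the natural scale
            sigma2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            x = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        if self.age_slope:
            x = x + self.age_slope * (ages - self.age_ref)
        return np.clip(x, self.lo, self.hi)


@dataclass(frozen=True)
class AgeBand:
    lo: float
    hi: float
    weight: float


@dataclass
class PopulationSpec:
    """Generative parameters of the synthetic smoker cohort."""

    strata_weights: dict[tuple[str, str], float]
    age_bands: Sequence[AgeBand]
    risk_factors: dict[str, RiskFactorSpec]
    diabetes_prevalence: dict[tuple[str, str], float]
    menthol_prevalence: dict[tuple[str, str], float]
    n_default: int = 10_000

    # -- validation -------------------------------------------------
    def issues(self, prefix: str = "population") -> list[str]:
        out: list[str] = []
        for cell in STRATA:
            for mapping, label in (
                (self.strata_weights, "strata_weights"),
                (self.diabetes_prevalence, "diabetes_prevalence"),
                (self.menthol_prevalence, "menthol_prevalence"),
            ):
                key = f"{prefix}.{label}.{cell[0]}.{cell[1]}"
                if cell not in mapping:
                    out.append(f"{key}: missing cell")
                    continue
                v = mapping[cell]
                if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                    out.append(f"{key}: value {v} outside [0, 1]")
        if all(c in self.strata_weights for c in STRATA):
            total = math.fsum(self.strata_weights[c] for c in STRATA)
            if abs(total - 1.0) > 1e-9:
                out.append(
                    f"{prefix}.strata_weights: cells sum to {total!r}, not 1"
                )
        if not self.age_bands:
            out.append(f"{prefix}.age_bands: empty")
        wsum = math.fsum(b.weight for b in self.age_bands)
        if self.age_bands and abs(wsum - 1.0) > 1e-9:
            out.append(f"{prefix}.age_bands: weights sum to {wsum!r}, not 1")
        for i, b in enumerate(self.age_bands):
            if b.lo < 18:
                out.append(f"{prefix}.age_bands[{i}].lo: below 18")
            if not b.lo < b.hi:
                out.append(f"{prefix}.age_bands[{i}]: lo must be < hi")
            if b.weight < 0:
                out.append(f"{prefix}.age_bands[{i}].weight: negative")
        for name in RISK_FACTOR_BOUNDS:
            if name not in self.risk_factors:
                out.append(f"{prefix}.risk_factors.{name}: missing")
        for name, rf in self.risk_factors.items():
            out.extend(rf.issues(f"{prefix}.risk_factors.{name}"))
            if name in RISK_FACTOR_BOUNDS:
                lo, hi = RISK_FACTOR_BOUNDS[name]
                if rf.lo < lo or rf.hi > hi:
                    out.append(
                        f"{prefix}.risk_factors.{name}: clamp [{rf.lo}, {rf.hi}] "
                        f"outside allowed [{lo}, {hi}]"
                    )
        if self.n_default < 1:
            out.append(f"{prefix}.n_default: must be >= 1")
        return out

    def validate(self) -> "PopulationSpec":
        issues = self.issues()
        if issues:
            raise ConfigError(issues)
        return self

    def with_menthol_cell(self, sex: str, race: str, value: float) -> "PopulationSpec":
        """Copy of the spec with one menthol-prevalence cell replaced."""
        prev = dict(self.menthol_prevalence)
        prev[(sex, race)] = value
        return replace(self, menthol_prevalence=prev)


class Cohort:
    """Column-oriented container for a population of :class:`PersonState`.

    Categorical fields are stored as small integer codes (see
    ``SEX_CODES`` etc.); ``death_cause`` is bookkeeping used by the
    simulation engine (-1 alive/never died, 0 non-CVD, 1 CVD) and is not
    part of the person-level CSV schema.
    """

    __slots__ = (
        "person_id", "age", "sex", "race", "bmi", "sbp", "ldl_c", "hdl_c",
        "diabetes", "smoking", "alive", "had_mi", "had_stroke",
        "discounted_cost", "death_cause",
    )

    def __init__(self, **arrays: np.ndarray):
        n = len(arrays["person_id"])
        for name in self.__slots__:
            if name == "death_cause" and name not in arrays:
                arrays[name] = np.full(n, -1, dtype=np.int8)
            a = np.asarray(arrays[name])
            if a.shape != (n,):
                raise ValueError(f"column {name} has shape {a.shape}, want ({n},)")
            setattr(self, name, a)

    def __len__(self) -> int:
        return int(self.person_id.shape[0])

    @property
    def n(self) -> int:
        return len(self)

    def copy(self) -> "Cohort":
        return Cohort(**{k: getattr(self, k).copy() for k in self.__slots__})

    def equals(self, other: "Cohort") -> bool:
        return all(
            np.array_equal(getattr(self, k), getattr(other, k))
            for k in self.__slots__
        )

    # -- row access --------------------------------------------------
    def person(self, i: int) -> PersonState:
        return PersonState(
            person_id=int(self.person_id[i]),
            age=float(self.age[i]),
            sex=SEXES[self.sex[i]],
            race_ethnicity=RACE_ETHNICITIES[self.race[i]],
            bmi=float(self.bmi[i]),
            sbp=float(self.sbp[i]),
            ldl_c=float(self.ldl_c[i]),
            hdl_c=float(self.hdl_c[i]),
            diabetes=bool(self.diabetes[i]),
            smoking_status=SMOKING_STATUSES[self.smoking[i]],
            alive=bool(self.alive[i]),
            had_mi=bool(self.had_mi[i]),
            had_stroke=bool(self.had_stroke[i]),
            discounted_cost=float(self.discounted_cost[i]),
        )

    def people(self) -> Iterable[PersonState]:
        return (self.person(i) for i in range(len(self)))

    # -- tabular interchange ----------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.person_id,
                "age": self.age,
                "sex": np.asarray(SEXES, dtype=object)[self.sex],
                "race_ethnicity": np.asarray(RACE_ETHNICITIES, dtype=object)[self.race],
                "bmi": self.bmi,
                "sbp": self.sbp,
                "ldl_c": self.ldl_c,
                "hdl_c": self.hdl_c,
                "diabetes": self.diabetes,
                "smoking_status": np.asarray(SMOKING_STATUSES, dtype=object)[self.smoking],
                "alive": self.alive,
                "had_mi": self.had_mi,
                "had_stroke": self.had_stroke,
                "discounted_cost": self.discounted_cost,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        missing = [c for c in PERSON_FIELDS if c not in df.columns]
        if missing:
            raise ConfigError([f"cohort csv: missing columns {missing}"])
        code = lambda col, table: np.asarray([table[v] for v in df[col]], dtype=np.int8)
        return cls(
            person_id=df["person_id"].to_numpy(np.int64),
            age=df["age"].to_numpy(np.float64),
            sex=code("sex", SEX_CODES),
            race=code("race_ethnicity", RACE_CODES),
            bmi=df["bmi"].to_numpy(np.float64),
            sbp=df["sbp"].to_numpy(np.float64),
            ldl_c=df["ldl_c"].to_numpy(np.float64),
            hdl_c=df["hdl_c"].to_numpy(np.float64),
            diabetes=df["diabetes"].to_numpy(bool),
            smoking=code("smoking_status", SMOKING_CODES),
            alive=df["alive"].to_numpy(bool),
            had_mi=df["had_mi"].to_numpy(bool),
            had_stroke=df["had_stroke"].to_numpy(bool),
            discounted_cost=df["discounted_cost"].to_numpy(np.float64),
        )

    def to_csv(self, path) -> None:
        # %.17g round-trips float64 exactly through text
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"))


def assign_menthol_status(
    sex: str,
    race_ethnicity: str,
    menthol_prevalence: dict[tuple[str, str], float],
    rng: np.random.Generator,
) -> str:
    """Draw a baseline smoking status for one person.

    Returns ``current_menthol`` with the probability configured for the
    ``(sex, race_ethnicity)`` cell, else ``current_nonmenthol``.
    """
    key = (sex, race_ethnicity)
    if key not in menthol_prevalence:
        raise ConfigError(
            [f"menthol_prevalence.{sex}.{race_ethnicity}: missing cell"]
        )
    p = menthol_prevalence[key]
    if not (0.0 <= p <= 1.0):
        raise ConfigError(
            [f"menthol_prevalence.{sex}.{race_ethnicity}: value {p} outside [0, 1]"]
        )
    return (
        SMOKING_STATUSES[CURRENT_MENTHOL]
        if rng.random() < p
        else SMOKING_STATUSES[CURRENT_NONMENTHOL]
    )


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, (list, tuple)):
        return np.random.SeedSequence([int(s) for s in seed])
    return np.random.SeedSequence(int(seed))


def generate_population(spec: PopulationSpec, n: int, seed) -> Cohort:
    """Generate ``n`` baseline smokers from a validated spec.

    Identical ``(spec, n, seed)`` produce a bitwise-identical cohort.
    Every person starts alive, event-free, with zero accumulated cost,
    and currently smoking (menthol or non-menthol per the prevalence
    matrix).  ``seed`` may be an int or a sequence of ints.
    """
    spec.validate()
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(_as_seed_sequence(seed))

    weights = np.array([spec.strata_weights[c] for c in STRATA], dtype=float)
    weights = weights / weights.sum()  # guard fp residue; validated to 1e-9
    stratum = rng.choice(len(STRATA), size=n, p=weights)
    sex = np.array([SEX_CODES[STRATA[k][0]] for k in range(len(STRATA))], dtype=np.int8)[stratum]
    race = np.array([RACE_CODES[STRATA[k][1]] for k in range(len(STRATA))], dtype=np.int8)[stratum]

    bw = np.array([b.weight for b in spec.age_bands], dtype=float)
    bw = bw / bw.sum()
    band = rng.choice(len(spec.age_bands), size=n, p=bw)
    lo = np.array([b.lo for b in spec.age_bands])[band]
    hi = np.array([b.hi for b in spec.age_bands])[band]
    age = lo + rng.random(n) * (hi - lo)

    factors = {
        name: spec.risk_factors[name].sample(rng, age)
        for name in ("bmi", "sbp", "ldl_c", "hdl_c")
    }

    diab_p = np.array([spec.diabetes_prevalence[STRATA[k]] for k in range(len(STRATA))])[stratum]
    diabetes = rng.random(n) < diab_p

    menth_p = np.array([spec.menthol_prevalence[STRATA[k]] for k in range(len(STRATA))])[stratum]
    smoking = np.where(rng.random(n) < menth_p, CURRENT_MENTHOL, CURRENT_NONMENTHOL).astype(np.int8)

    return Cohort(
        person_id=np.arange(n, dtype=np.int64),
        age=age.astype(np.float64),
        sex=sex,
        race=race,
        bmi=factors["bmi"],
        sbp=factors["sbp"],
        ldl_c=factors["ldl_c"],
        hdl_c=factors["hdl_c"],
        diabetes=diabetes,
        smoking=smoking,
        alive=np.ones(n, dtype=bool),
        had_mi=np.zeros(n, dtype=bool),
        had_stroke=np.zeros(n, dtype=bool),
        discounted_cost=np.zeros(n, dtype=np.float64),
    )
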