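"""Loading and validation of the YAML model configuration.

All model parameters — the population spec, the three outcome
coefficient sets, the life table, the cost block and the scenario list
— enter through one YAML file.  :func:`validate_config` collects every
invariant violation across all sections and reports them together,
each prefixed with a dotted locator for the offending key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .costs import CostParameters
from .engine import ModelSuite
from .errors import ConfigError
from .policy import PolicyScenario
from .population import (
    AgeBand,
    PopulationSpec,
    RACE_ETHNICITIES,
    RiskFactorSpec,
    SEXES,
)
from .risk import LifeTable, RiskCoefficients


@dataclass
class AppConfig:
    """Everything a run needs, parsed and validated."""

    population: PopulationSpec
    models: ModelSuite
    scenarios: list[PolicyScenario]
    population_size: float = 880_000.0
    raw: dict = field(default_factory=dict, repr=False)

    def scenario(self, name: str) -> PolicyScenario:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise ConfigError([f"scenarios: no scenario named {name!r}"])

    def config_hash(self) -> str:
        """Stable digest of the parsed configuration content."""
        blob = json.dumps(self.raw, sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()


def default_config_path() -> Path:
    return Path(resources.files("mentholsim") / "data" / "default_config.yaml")


def _cell_map(section, issues, loc) -> dict:
    out = {}
    if not isinstance(section, dict):
        issues.append(f"{loc}: expected a mapping of sex -> race -> value")
        return out
    for sex in SEXES:
        for race in RACE_ETHNICITIES:
            try:
                out[(sex, race)] = float(section[sex][race])
            except (KeyError, TypeError):
                issues.append(f"{loc}.{sex}.{race}: missing cell")
            except ValueError:
                issues.append(f"{loc}.{sex}.{race}: not a number")
    return out


def _parse_population(doc, issues) -> PopulationSpec | None:
    sec = doc.get("population")
    if sec is None:
        issues.append("population: missing section")
        return None
    strata = _cell_map(sec.get("strata_weights"), issues, "population.strata_weights")
    diab = _cell_map(sec.get("diabetes_prevalence"), issues, "population.diabetes_prevalence")
    menthol = _cell_map(sec.get("menthol_prevalence"), issues, "population.menthol_prevalence")
    bands = []
    for i, row in enumerate(sec.get("age_bands", []) or []):
        try:
            bands.append(AgeBand(float(row["lo"]), float(row["hi"]), float(row["weight"])))
        except (KeyError, TypeError, ValueError):
            issues.append(f"population.age_bands[{i}]: need numeric lo, hi, weight")
    factors = {}
    for name, row in (sec.get("risk_factors") or {}).items():
        try:
            factors[name] = RiskFactorSpec(
                family=str(row["family"]),
                mean=float(row["mean"]),
                sd=float(row["sd"]),
                lo=float(row["lo"]),
                hi=float(row["hi"]),
                age_slope=float(row.get("age_slope", 0.0)),
                age_ref=float(row.get("age_ref", 45.0)),
            )
        except (KeyError, TypeError, ValueError):
            issues.append(
                f"population.risk_factors.{name}: need family, mean, sd, lo, hi"
            )
    spec = PopulationSpec(
        strata_weights=strata,
        age_bands=bands,
        risk_factors=factors,
        diabetes_prevalence=diab,
        menthol_prevalence=menthol,
        n_default=int(sec.get("n_default", 10_000)),
    )
    issues.extend(spec.issues())
    return spec


def _parse_models(doc, issues) -> ModelSuite | None:
    coeffs = {}
    sec = doc.get("coefficients")
    if sec is None:
        issues.append("coefficients: missing section")
    else:
        for outcome, block in sec.items():
            try:
                coeffs[outcome] = RiskCoefficients(
                    outcome=outcome,
                    alpha=float(block["alpha"]),
                    betas={k: float(v) for k, v in (block.get("betas") or {}).items()},
                )
            except (KeyError, TypeError, ValueError):
                issues.append(f"coefficients.{outcome}: need alpha and a betas mapping")
    lt_sec = doc.get("life_table")
    bands = {}
    if lt_sec is None:
        issues.append("life_table: missing section")
    else:
        for sex in SEXES:
            rows = []
            for i, row in enumerate(lt_sec.get(sex, []) or []):
                try:
                    rows.append((float(row["lo"]), float(row["hi"]), float(row["q"])))
                except (KeyError, TypeError, ValueError):
                    issues.append(f"life_table.{sex}[{i}]: need numeric lo, hi, q")
            bands[sex] = rows
    life_table = LifeTable(bands=bands)

    cost_sec = doc.get("costs")
    if cost_sec is None:
        issues.append("costs: missing section")
        costs = CostParameters(background_costs=[], mi_event_cost=0, stroke_event_cost=0)
    else:
        bg = []
        for i, row in enumerate(cost_sec.get("background", []) or []):
            try:
                bg.append((float(row["lo"]), float(row["hi"]), float(row["cost"])))
            except (KeyError, TypeError, ValueError):
                issues.append(f"costs.background[{i}]: need numeric lo, hi, cost")
        try:
            costs = CostParameters(
                background_costs=bg,
                mi_event_cost=float(cost_sec.get("mi_event_cost", 0.0)),
                stroke_event_cost=float(cost_sec.get("stroke_event_cost", 0.0)),
                post_mi_annual_cost=float(cost_sec.get("post_mi_annual_cost", 0.0)),
                post_stroke_annual_cost=float(cost_sec.get("post_stroke_annual_cost", 0.0)),
                discount_rate=float(cost_sec.get("discount_rate", 0.03)),
                base_year_index=int(cost_sec.get("base_year_index", 0)),
            )
        except (TypeError, ValueError):
            issues.append("costs: non-numeric cost parameter")
            costs = CostParameters(background_costs=bg, mi_event_cost=0, stroke_event_cost=0)

    suite = ModelSuite(coefficients=coeffs, life_table=life_table, costs=costs)
    issues.extend(suite.issues())
    return suite


def _parse_scenarios(doc, issues) -> list[PolicyScenario]:
    out = []
    sec = doc.get("scenarios")
    if not sec:
        issues.append("scenarios: missing or empty section")
        return out
    for i, row in enumerate(sec):
        try:
            s = PolicyScenario(
                name=str(row["name"]),
                quit_proportion=float(row.get("quit_proportion", 0.0)),
                start_year_index=int(row.get("start_year_index", 0)),
            )
        except (KeyError, TypeError, ValueError):
            issues.append(f"scenarios[{i}]: need name and numeric quit_proportion")
            continue
        issues.extend(s.issues(prefix="scenarios"))
        out.append(s)
    return out


def load_config(path: str | Path | None = None) -> AppConfig:
    """Parse and fully validate a config file (the packaged default if
    ``path`` is None).  Raises :class:`ConfigError` listing *all*
    violations found."""
    p = Path(path) if path is not None else default_config_path()
    try:
        doc = yaml.safe_load(p.read_text())
    except FileNotFoundError:
        raise ConfigError([f"{p}: file not found"])
    except yaml.YAMLError as e:
        raise ConfigError([f"{p}: YAML parse error: {e}"])
    if not isinstance(doc, dict):
        raise ConfigError([f"{p}: top level must be a mapping"])

    issues: list[str] = []
    population = _parse_population(doc, issues)
    models = _parse_models(doc, issues)
    scenarios = _parse_scenarios(doc, issues)
    try:
        population_size = float(doc.get("population_size", 880_000))
        if population_size < 0:
            issues.append("population_size: must be >= 0")
    except (TypeError, ValueError):
        issues.append("population_size: not a number")
        population_size = 0.0
    if issues:
        raise ConfigError(issues)
    return AppConfig(
        population=population,
        models=models,
        scenarios=scenarios,
        population_size=population_size,
        raw=doc,
    )


def validate_config(path: str | Path | None = None) -> AppConfig:
    """Alias of :func:`load_config`; kept as the explicit validation entry."""
    return load_config(path)
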