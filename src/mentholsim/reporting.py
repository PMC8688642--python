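"""Aggregation of replicate results into headline policy quantities.

Turns collections of :class:`~mentholsim.engine.ScenarioResult` into
the numbers a policy evaluation reports: cumulative events per million
adults with percentile confidence intervals, averted cases and percent
reductions under the ban, per-person and citywide cost savings, subgroup
(sex-by-race/ethnicity) disparity tables, and the averted-cases curve
across candidate quit proportions.  Internal arithmetic is never
rounded; rounding is applied only in the display helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ModelSuite, ScenarioResult, run_replicates
from .errors import ConfigError
from .policy import PolicyScenario
from .population import STRATA, PopulationSpec

logger = logging.getLogger(__name__)

PER_MILLION = 1_000_000
DEFAULT_POPULATION_SIZE = 880_000


def per_million(count: float, n_simulated: int) -> float:
    """Scale a cohort tally to a rate per one million adults."""
    if n_simulated < 1:
        raise ConfigError(["per_million: n_simulated must be >= 1"])
    return count * PER_MILLION / n_simulated


def prevalence_pct(count: float, total: float) -> float:
    """A share expressed in percent (e.g. menthol smokers among all smokers)."""
    return 100.0 * count / total


def averted_and_reduction(status_quo: float, ban: float) -> tuple[float, float | None]:
    """Averted cases per million and the percent reduction they represent.

    Returns ``(status_quo - ban, 100 * averted / status_quo)``; the
    percent reduction is ``None`` when the status-quo rate is zero.
    """
    averted = status_quo - ban
    if status_quo == 0:
        return averted, None
    return averted, 100.0 * averted / status_quo


def cost_savings(
    status_quo_per_person: float, ban_per_person: float, population: float
) -> tuple[float, float]:
    """Per-person saving and its citywide total for a smoker population."""
    if population < 0:
        raise ConfigError(["cost_savings: population must be >= 0"])
    diff = status_quo_per_person - ban_per_person
    return diff, diff * population


def percentile_ci(values, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """Monte-Carlo interval from the replicate distribution."""
    arr = np.asarray(values, dtype=float)
    return float(np.percentile(arr, lo)), float(np.percentile(arr, hi))


@dataclass
class ScenarioSummary:
    """Replicate-mean rates for one scenario, with percentile CIs."""

    scenario: str
    replicates: int
    mi_per_million: float
    mi_ci: tuple[float, float]
    stroke_per_million: float
    stroke_ci: tuple[float, float]
    cost_per_person: float
    cost_ci: tuple[float, float]


@dataclass
class ComparisonReport:
    """Headline comparison of the ban against the status quo."""

    status_quo: ScenarioSummary
    ban: ScenarioSummary
    averted_mi_per_million: float
    averted_stroke_per_million: float
    pct_reduction_mi: float | None
    pct_reduction_stroke: float | None
    per_person_saving: float
    total_saving: float
    population_size: float

    def to_dict(self) -> dict:
        def scen(s: ScenarioSummary) -> dict:
            return {
                "scenario": s.scenario,
                "replicates": s.replicates,
                "mi_per_million": s.mi_per_million,
                "mi_ci": list(s.mi_ci),
                "stroke_per_million": s.stroke_per_million,
                "stroke_ci": list(s.stroke_ci),
                "cost_per_person": s.cost_per_person,
                "cost_ci": list(s.cost_ci),
            }

        return {
            "status_quo": scen(self.status_quo),
            "ban": scen(self.ban),
            "averted_mi_per_million": self.averted_mi_per_million,
            "averted_stroke_per_million": self.averted_stroke_per_million,
            "pct_reduction_mi": self.pct_reduction_mi,
            "pct_reduction_stroke": self.pct_reduction_stroke,
            "per_person_saving": self.per_person_saving,
            "total_saving": self.total_saving,
            "population_size": self.population_size,
        }

    def to_frame(self) -> pd.DataFrame:
        """Table shaped like the headline results table (one scenario per row)."""
        rows = []
        for s, averted_mi, averted_st, saving in (
            (self.status_quo, None, None, None),
            (self.ban, self.averted_mi_per_million, self.averted_stroke_per_million,
             self.per_person_saving),
        ):
            rows.append(
                {
                    "scenario": s.scenario,
                    "mi_per_million": s.mi_per_million,
                    "mi_ci_lo": s.mi_ci[0],
                    "mi_ci_hi": s.mi_ci[1],
                    "averted_mi_per_million": averted_mi,
                    "stroke_per_million": s.stroke_per_million,
                    "stroke_ci_lo": s.stroke_ci[0],
                    "stroke_ci_hi": s.stroke_ci[1],
                    "averted_stroke_per_million": averted_st,
                    "cost_per_person": s.cost_per_person,
                    "cost_ci_lo": s.cost_ci[0],
                    "cost_ci_hi": s.cost_ci[1],
                    "saving_per_person": saving,
                }
            )
        return pd.DataFrame(rows)


def _summarize_scenario(results: list[ScenarioResult]) -> ScenarioSummary:
    if not results:
        raise ConfigError(["summarize: no results for scenario"])
    name = results[0].scenario
    mi = [per_million(r.mi, r.n_simulated) for r in results]
    st = [per_million(r.stroke, r.n_simulated) for r in results]
    cost = [r.cost / r.n_simulated for r in results]
    return ScenarioSummary(
        scenario=name,
        replicates=len(results),
        mi_per_million=float(np.mean(mi)),
        mi_ci=percentile_ci(mi),
        stroke_per_million=float(np.mean(st)),
        stroke_ci=percentile_ci(st),
        cost_per_person=float(np.mean(cost)),
        cost_ci=percentile_ci(cost),
    )


def split_by_scenario(results: list[ScenarioResult]) -> dict[str, list[ScenarioResult]]:
    out: dict[str, list[ScenarioResult]] = {}
    for r in results:
        out.setdefault(r.scenario, []).append(r)
    for rs in out.values():
        rs.sort(key=lambda r: r.replicate_id)
    return out


def summarize(
    results: list[ScenarioResult],
    status_quo: str = "status_quo",
    ban: str = "menthol_ban",
    population_size: float = DEFAULT_POPULATION_SIZE,
) -> ComparisonReport:
    """Build the headline comparison from paired replicate results."""
    by = split_by_scenario(results)
    for name in (status_quo, ban):
        if name not in by:
            raise ConfigError([f"summarize: scenario {name!r} absent from results"])
    sq = _summarize_scenario(by[status_quo])
    bn = _summarize_scenario(by[ban])
    averted_mi, red_mi = averted_and_reduction(sq.mi_per_million, bn.mi_per_million)
    averted_st, red_st = averted_and_reduction(sq.stroke_per_million, bn.stroke_per_million)
    saving, total = cost_savings(sq.cost_per_person, bn.cost_per_person, population_size)
    return ComparisonReport(
        status_quo=sq,
        ban=bn,
        averted_mi_per_million=averted_mi,
        averted_stroke_per_million=averted_st,
        pct_reduction_mi=red_mi,
        pct_reduction_stroke=red_st,
        per_person_saving=saving,
        total_saving=total,
        population_size=population_size,
    )


def subgroup_report(
    results: list[ScenarioResult],
    status_quo: str = "status_quo",
    ban: str = "menthol_ban",
) -> pd.DataFrame:
    """Per-(sex, race/ethnicity) percent reductions and per-person savings.

    Percent reductions are within-cell (cell averted over cell
    status-quo events), i.e. each subgroup is compared against its own
    baseline burden.  One row per cell; cells with no simulated persons
    or no status-quo events yield missing values and a logged warning.
    """
    by = split_by_scenario(results)
    sq_runs, bn_runs = by.get(status_quo, []), by.get(ban, [])
    if len(sq_runs) != len(bn_runs) or not sq_runs:
        raise ConfigError(["subgroup_report: need paired status-quo and ban replicates"])
    rows = []
    for cell in STRATA:
        sq_mi = np.array([r.subgroups[cell].mi for r in sq_runs], dtype=float)
        bn_mi = np.array([r.subgroups[cell].mi for r in bn_runs], dtype=float)
        sq_st = np.array([r.subgroups[cell].stroke for r in sq_runs], dtype=float)
        bn_st = np.array([r.subgroups[cell].stroke for r in bn_runs], dtype=float)
        sq_cost = np.array([r.subgroups[cell].cost for r in sq_runs], dtype=float)
        bn_cost = np.array([r.subgroups[cell].cost for r in bn_runs], dtype=float)
        ns = np.array([r.subgroups[cell].n for r in sq_runs], dtype=float)

        row: dict = {"sex": cell[0], "race_ethnicity": cell[1], "mean_n": float(ns.mean())}
        if ns.sum() == 0:
            logger.warning("subgroup %s/%s is empty; reporting missing values", *cell)
            row.update(
                mi_reduction_pct=np.nan, stroke_reduction_pct=np.nan,
                saving_per_person=np.nan, averted_mi=np.nan, averted_stroke=np.nan,
            )
        else:
            row["averted_mi"] = float((sq_mi - bn_mi).mean())
            row["averted_stroke"] = float((sq_st - bn_st).mean())
            row["mi_reduction_pct"] = (
                100.0 * (sq_mi.mean() - bn_mi.mean()) / sq_mi.mean()
                if sq_mi.mean() > 0 else np.nan
            )
            row["stroke_reduction_pct"] = (
                100.0 * (sq_st.mean() - bn_st.mean()) / sq_st.mean()
                if sq_st.mean() > 0 else np.nan
            )
            row["saving_per_person"] = float(((sq_cost - bn_cost) / ns).mean())
            if np.isnan(row["mi_reduction_pct"]) or np.isnan(row["stroke_reduction_pct"]):
                logger.warning(
                    "subgroup %s/%s has no status-quo events; reduction undefined", *cell
                )
        rows.append(row)
    return pd.DataFrame(rows)


def quit_proportion_sweep(
    proportions: list[float],
    spec: PopulationSpec,
    models: ModelSuite,
    n: int = 10_000,
    horizon: int = 20,
    seed: int = 0,
    replicates: int = 20,
) -> pd.DataFrame:
    """Averted MI/stroke per million as a function of the quit proportion.

    Every proportion is run against the same status-quo baseline with
    shared cohorts and uniform streams, so the curve is a paired
    comparison throughout (and exactly zero at proportion 0).
    """
    bad = [p for p in proportions if not (0.0 <= p <= 1.0)]
    if bad:
        raise ConfigError([f"quit_proportion_sweep: proportions outside [0, 1]: {bad}"])
    scenarios = [PolicyScenario(name="status_quo", quit_proportion=0.0)] + [
        PolicyScenario(name=f"ban_q{p:g}", quit_proportion=p) for p in proportions
    ]
    results = run_replicates(
        spec, scenarios, models, n=n, horizon=horizon,
        base_seed=seed, replicates=replicates,
    )
    by = split_by_scenario(results)
    sq = by["status_quo"]
    rows = []
    for p in proportions:
        runs = by[f"ban_q{p:g}"]
        averted_mi = np.mean(
            [per_million(s.mi - b.mi, s.n_simulated) for s, b in zip(sq, runs)]
        )
        averted_st = np.mean(
            [per_million(s.stroke - b.stroke, s.n_simulated) for s, b in zip(sq, runs)]
        )
        rows.append(
            {
                "quit_proportion": p,
                "averted_mi_per_million": float(averted_mi),
                "averted_stroke_per_million": float(averted_st),
            }
        )
    return pd.DataFrame(rows)


def results_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format per-replicate table: one row per scenario x replicate x
    subgroup, plus an ``overall`` row per scenario x replicate."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario, "replicate_id": r.replicate_id,
                "sex": "overall", "race_ethnicity": "overall",
                "n": r.n_simulated, "mi": r.mi, "stroke": r.stroke,
                "cvd_deaths": r.cvd_deaths, "non_cvd_deaths": r.non_cvd_deaths,
                "discounted_cost": r.cost,
            }
        )
        for (sex, race), t in r.subgroups.items():
            rows.append(
                {
                    "scenario": r.scenario, "replicate_id": r.replicate_id,
                    "sex": sex, "race_ethnicity": race,
                    "n": t.n, "mi": t.mi, "stroke": t.stroke,
                    "cvd_deaths": t.cvd_deaths, "non_cvd_deaths": t.non_cvd_deaths,
                    "discounted_cost": t.cost,
                }
            )
    return pd.DataFrame(rows)


# display rounding conventions: per-million counts and dollars to
# integers, billions to two decimals, percents to one decimal
def rounded_headlines(report: ComparisonReport) -> dict:
    return {
        "mi_per_million_status_quo": round(report.status_quo.mi_per_million),
        "stroke_per_million_status_quo": round(report.status_quo.stroke_per_million),
        "mi_per_million_ban": round(report.ban.mi_per_million),
        "stroke_per_million_ban": round(report.ban.stroke_per_million),
        "averted_mi_per_million": round(report.averted_mi_per_million),
        "averted_stroke_per_million": round(report.averted_stroke_per_million),
        "pct_reduction_mi": (
            None if report.pct_reduction_mi is None else round(report.pct_reduction_mi, 1)
        ),
        "pct_reduction_stroke": (
            None if report.pct_reduction_stroke is None else round(report.pct_reduction_stroke, 1)
        ),
        "per_person_saving": round(report.per_person_saving),
        "total_saving_billion": round(report.total_saving / 1e9, 2),
    }
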