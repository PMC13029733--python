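"""Result tables, run manifests, and the high-level pipeline entry point.

`run_pipeline` loads (or synthesises) a parameter set, simulates the
requested scenarios, and writes four CSV tables plus a JSON manifest to
an output directory:

* ``base_case.csv`` — cumulative cases, deaths and expenditure per stratum;
* ``prevented.csv`` — cases/deaths prevented per intervention scenario;
* ``savings.csv`` — discounted expenditure savings per scenario;
* ``sensitivity.csv`` — one-way sensitivity intervals (optional);
* ``manifest.json`` — everything needed to reproduce the run.

Numbers are written unrounded; display rounding happens only in the
console summary.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .parameters import ModelConfig, ParameterSet, Sex, load_parameter_set
from .pipeline import ALL_SCENARIOS, SimulationResult, simulate
from .scenarios import SCENARIO_1, SCENARIO_2, ScenarioName, ScenarioSpec
from .sensitivity import sensitivity_report
from .synthetic import GeneratorConfig, generate_parameter_set

__all__ = [
    "base_case_table",
    "prevented_table",
    "savings_table",
    "run_pipeline",
    "format_summary",
]

_INTERVENTIONS = (SCENARIO_1, SCENARIO_2)


def _group_rows(result: SimulationResult):
    """Yield (sex_label, age_band, strata subset) for strata, sex totals, overall."""
    strata = sorted(result.base.trajectories, key=lambda s: (s.sex.value, s.age_band))
    for s in strata:
        yield s.sex.value, s.age_band, [s]
    for sex in (Sex.MEN, Sex.WOMEN):
        subset = [s for s in strata if s.sex == sex]
        if subset:
            yield sex.value, "30-79", subset
    yield "both", "30-79", strata


def base_case_table(result: SimulationResult) -> pd.DataFrame:
    """Cumulative base-case cases, deaths, and discounted expenditure."""
    base = result.base
    rows = []
    for sex, band, subset in _group_rows(result):
        pop = sum(base.trajectories[s].occupancy_by_cycle[0].total for s in subset)
        cases = sum(base.trajectories[s].cumulative_first_events for s in subset)
        deaths = sum(base.trajectories[s].cumulative_first_event_deaths for s in subset)
        nhe = sum(base.expenditures[s].cumulative_cost for s in subset)
        rows.append(
            {
                "sex": sex,
                "age_band": band,
                "population": pop,
                "cases": cases,
                "cases_pct": 100.0 * cases / pop,
                "deaths": deaths,
                "deaths_pct": 100.0 * deaths / pop,
                "nhe_usd": nhe,
            }
        )
    return pd.DataFrame(rows)


def prevented_table(result: SimulationResult) -> pd.DataFrame:
    """Cases and deaths prevented by each intervention scenario."""
    base = result.base
    rows = []
    for name, outcome in result.outcomes.items():
        if name is ScenarioName.BASE_CASE:
            continue
        for sex, band, subset in _group_rows(result):
            b_cases = sum(base.trajectories[s].cumulative_first_events for s in subset)
            b_deaths = sum(base.trajectories[s].cumulative_first_event_deaths for s in subset)
            i_cases = sum(outcome.trajectories[s].cumulative_first_events for s in subset)
            i_deaths = sum(outcome.trajectories[s].cumulative_first_event_deaths for s in subset)
            rows.append(
                {
                    "scenario": name.value,
                    "sex": sex,
                    "age_band": band,
                    "base_cases": b_cases,
                    "prevented_cases": b_cases - i_cases,
                    "prevented_cases_pct": 100.0 * (b_cases - i_cases) / b_cases,
                    "base_deaths": b_deaths,
                    "prevented_deaths": b_deaths - i_deaths,
                    "prevented_deaths_pct": 100.0 * (b_deaths - i_deaths) / b_deaths,
                }
            )
    return pd.DataFrame(rows)


def savings_table(result: SimulationResult) -> pd.DataFrame:
    """Discounted expenditure savings by each intervention scenario."""
    base = result.base
    rows = []
    for name, outcome in result.outcomes.items():
        if name is ScenarioName.BASE_CASE:
            continue
        for sex, band, subset in _group_rows(result):
            b = sum(base.expenditures[s].cumulative_cost for s in subset)
            i = sum(outcome.expenditures[s].cumulative_cost for s in subset)
            rows.append(
                {
                    "scenario": name.value,
                    "sex": sex,
                    "age_band": band,
                    "base_usd": b,
                    "savings_usd": b - i,
                    "savings_pct": 100.0 * (b - i) / b,
                }
            )
    return pd.DataFrame(rows)


def format_summary(result: SimulationResult) -> str:
    """Human-readable overall summary (counts to integers, percents to one decimal)."""
    base = result.base
    lines = [
        "Base case (10-year cumulative, both sexes):",
        f"  stroke cases:  {base.cumulative_cases():,.0f}",
        f"  stroke deaths: {base.cumulative_deaths():,.0f}",
        f"  stroke NHE:    USD {base.cumulative_nhe():,.0f}",
    ]
    for name in result.outcomes:
        if name is ScenarioName.BASE_CASE:
            continue
        pc = result.prevented_cases(name)
        pd_ = result.prevented_deaths(name)
        sv = result.nhe_savings(name)
        lines.append(f"{name.value}:")
        lines.append(
            f"  prevented cases:  {pc:,.0f} ({100 * pc / base.cumulative_cases():.1f}%)"
        )
        lines.append(
            f"  prevented deaths: {pd_:,.0f} ({100 * pd_ / base.cumulative_deaths():.1f}%)"
        )
        lines.append(
            f"  NHE savings:      USD {sv:,.0f} ({100 * sv / base.cumulative_nhe():.1f}%)"
        )
        for sex in (Sex.MEN, Sex.WOMEN):
            lines.append(
                f"    {sex.value}: {result.prevented_cases(name, sex):,.0f} cases, "
                f"{result.prevented_deaths(name, sex):,.0f} deaths, "
                f"USD {result.nhe_savings(name, sex):,.0f}"
            )
    return "\n".join(lines)


def run_pipeline(
    params_source: Union[str, Path] = "paper2023",
    out_dir: Union[str, Path] = "milkstroke_out",
    scenarios: Sequence[ScenarioSpec] = ALL_SCENARIOS,
    config: Optional[ModelConfig] = None,
    run_sensitivity: bool = True,
    seed: Optional[int] = None,
) -> SimulationResult:
    """Run the model end to end and write result tables plus a manifest.

    ``params_source`` is a fixture name, a parameter-file path, or the
    literal ``"synthetic"`` (which requires ``seed``).
    """
    if params_source == "synthetic":
        if seed is None:
            raise ValueError("synthetic parameters require a seed")
        pset = generate_parameter_set(GeneratorConfig(seed=seed))
    else:
        pset = load_parameter_set(params_source)
    cfg = config if config is not None else pset.config

    result = simulate(pset, scenarios=scenarios, config=cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_case_table(result).to_csv(out / "base_case.csv", index=False)
    if len(result.outcomes) > 1:
        prevented_table(result).to_csv(out / "prevented.csv", index=False)
        savings_table(result).to_csv(out / "savings.csv", index=False)
    if run_sensitivity:
        interventions = [s for s in scenarios if s.name is not ScenarioName.BASE_CASE]
        if interventions:
            sensitivity_report(pset, scenarios=interventions, config=cfg).to_csv(
                out / "sensitivity.csv", index=False
            )
    manifest = {
        "params_source": str(params_source),
        "scenarios": [name.value for name in result.outcomes],
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
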