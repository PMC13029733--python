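"""End-to-end orchestration: run every stratum under one or more scenarios.

The base case is always simulated first because unit costs are
calibrated against it; intervention scenarios then reuse the same unit
costs so expenditure differences isolate the intervention effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .economics import (
    ExpenditureResult,
    UnitCosts,
    accrue_costs,
    calibrate_unit_costs,
)
from .markov import CohortTrajectory, run_cohort
from .parameters import ModelConfig, ParameterSet, Sex, Stratum
from .scenarios import BASE_CASE, SCENARIO_1, SCENARIO_2, ScenarioName, ScenarioSpec

__all__ = ["ScenarioOutcome", "SimulationResult", "simulate", "ALL_SCENARIOS"]

ALL_SCENARIOS: tuple[ScenarioSpec, ...] = (BASE_CASE, SCENARIO_1, SCENARIO_2)


@dataclass(frozen=True)
class ScenarioOutcome:
    """All per-stratum trajectories and expenditures for one scenario."""

    scenario: ScenarioName
    trajectories: Mapping[Stratum, CohortTrajectory]
    expenditures: Mapping[Stratum, ExpenditureResult]

    def _select(self, sex: Optional[Sex]) -> list[Stratum]:
        return [s for s in self.trajectories if sex is None or s.sex == sex]

    def cumulative_cases(self, sex: Optional[Sex] = None) -> float:
        return sum(self.trajectories[s].cumulative_first_events for s in self._select(sex))

    def cumulative_deaths(self, sex: Optional[Sex] = None) -> float:
        return sum(self.trajectories[s].cumulative_first_event_deaths for s in self._select(sex))

    def cumulative_nhe(self, sex: Optional[Sex] = None) -> float:
        return sum(self.expenditures[s].cumulative_cost for s in self._select(sex))


@dataclass(frozen=True)
class SimulationResult:
    """Outcomes keyed by scenario, sharing one unit-cost calibration."""

    outcomes: Mapping[ScenarioName, ScenarioOutcome]
    unit_costs: Mapping[Stratum, UnitCosts]
    config: ModelConfig

    def __getitem__(self, name: ScenarioName) -> ScenarioOutcome:
        return self.outcomes[name]

    @property
    def base(self) -> ScenarioOutcome:
        return self.outcomes[ScenarioName.BASE_CASE]

    def prevented_cases(self, scenario: ScenarioName, sex: Optional[Sex] = None) -> float:
        return self.base.cumulative_cases(sex) - self[scenario].cumulative_cases(sex)

    def prevented_deaths(self, scenario: ScenarioName, sex: Optional[Sex] = None) -> float:
        return self.base.cumulative_deaths(sex) - self[scenario].cumulative_deaths(sex)

    def nhe_savings(self, scenario: ScenarioName, sex: Optional[Sex] = None) -> float:
        return self.base.cumulative_nhe(sex) - self[scenario].cumulative_nhe(sex)


def simulate(
    params: ParameterSet,
    scenarios: Sequence[ScenarioSpec] = ALL_SCENARIOS,
    config: Optional[ModelConfig] = None,
    strata: Optional[Iterable[Stratum]] = None,
) -> SimulationResult:
    """Run the full model for the requested scenarios.

    ``config`` overrides ``params.config`` (e.g. for discount-rate
    sensitivity); ``strata`` restricts the run (e.g. to one sex).
    """
    cfg = config if config is not None else params.config
    selected = tuple(strata) if strata is not None else tuple(params.strata)
    specs = {s.name: s for s in scenarios}
    specs.setdefault(ScenarioName.BASE_CASE, BASE_CASE)

    def run_one(spec: ScenarioSpec) -> dict[Stratum, CohortTrajectory]:
        return {
            s: run_cohort(params.strata[s], params.sex_level[s.sex], params.dose, spec, cfg)
            for s in selected
        }

    base_traj = run_one(specs[ScenarioName.BASE_CASE])
    unit_costs = {s: calibrate_unit_costs(params.costs[s], base_traj[s]) for s in selected}

    outcomes: dict[ScenarioName, ScenarioOutcome] = {}
    for name, spec in specs.items():
        traj = base_traj if name is ScenarioName.BASE_CASE else run_one(spec)
        exp = {s: accrue_costs(traj[s], unit_costs[s], cfg) for s in selected}
        outcomes[name] = ScenarioOutcome(name, traj, exp)
    return SimulationResult(outcomes=outcomes, unit_costs=unit_costs, config=cfg)
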