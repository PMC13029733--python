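"""Intervention scenarios: intake trajectories and effective relative risk.

Three scenarios are modelled.  The base case holds each stratum's 2023
mean dairy intake constant.  Scenario 1 raises milk intake immediately
to the recommended dairy level (180 g/day by default).  Scenario 2 grows
intake by a constant annual factor so the target is first reached in the
final simulation year: with a 10-year horizon, intake sits at baseline
in year 1 and reaches the target after nine growth steps.

The protective dose-response is a published relative risk per fixed
milk increment (0.82 per 200 g/day).  It is rescaled to arbitrary
increments by the standard log-linear (power) convention,
``RR_eff = RR ** (increment / 200)``, and applied only to intake gained
above the stratum's baseline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .parameters import DoseResponse, ModelConfig, Stratum, StratumParameters

__all__ = [
    "ScenarioName",
    "ScenarioSpec",
    "IntakeTrajectory",
    "BASE_CASE",
    "SCENARIO_1",
    "SCENARIO_2",
    "growth_factor",
    "build_trajectory",
    "effective_relative_risk",
]


class ScenarioName(str, enum.Enum):
    BASE_CASE = "base_case"
    SCENARIO_1 = "scenario1_immediate"
    SCENARIO_2 = "scenario2_growth"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario; ``target_intake`` is ignored by the base case."""

    name: ScenarioName
    target_intake: float = 180.0


BASE_CASE = ScenarioSpec(ScenarioName.BASE_CASE)
SCENARIO_1 = ScenarioSpec(ScenarioName.SCENARIO_1)
SCENARIO_2 = ScenarioSpec(ScenarioName.SCENARIO_2)


@dataclass(frozen=True)
class IntakeTrajectory:
    """Per-cycle milk-intake targets (g/day) for one stratum."""

    stratum: Stratum
    intake_by_cycle: tuple[float, ...]


def growth_factor(baseline: float, target: float, horizon: int) -> float:
    """Constant annual multiplicative factor of the gradual-growth scenario.

    The first cycle sits at ``baseline`` and the ``horizon``-th cycle
    reaches ``target`` after ``horizon - 1`` growth steps, so the factor
    is ``(target / baseline) ** (1 / (horizon - 1))``.
    """
    if horizon < 2:
        raise ValueError(f"growth requires horizon >= 2 cycles, got {horizon}")
    if not baseline > 0:
        raise ValueError(f"baseline intake must be > 0, got {baseline}")
    if target < baseline:
        raise ValueError(
            f"intake reduction is out of scope: target {target} < baseline {baseline}"
        )
    return (target / baseline) ** (1.0 / (horizon - 1))


def build_trajectory(
    spec: ScenarioSpec, params: StratumParameters, config: ModelConfig
) -> IntakeTrajectory:
    """Per-cycle intake under ``spec`` for one stratum."""
    baseline = params.dairy_intake_mean
    horizon = config.horizon_cycles
    target = spec.target_intake if spec.target_intake is not None else config.target_intake
    if spec.name is ScenarioName.BASE_CASE:
        values = (baseline,) * horizon
    elif spec.name is ScenarioName.SCENARIO_1:
        if baseline > target:
            raise ValueError(
                f"{params.stratum.label}: baseline intake {baseline} exceeds target {target}"
            )
        values = (target,) * horizon
    elif spec.name is ScenarioName.SCENARIO_2:
        g = growth_factor(baseline, target, horizon)
        values = tuple(baseline * g**k for k in range(horizon))
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown scenario {spec.name}")
    return IntakeTrajectory(stratum=params.stratum, intake_by_cycle=values)


def effective_relative_risk(
    dose: DoseResponse, baseline_intake: float, scenario_intake: float
) -> float:
    """Relative risk for the intake increment above baseline.

    Only intake gained above the baseline mean carries the protective
    effect; the risk already embodied in the observed rates corresponds
    to baseline consumption.  Equals 1 when there is no increment, and
    is multiplicative in stacked increments.
    """
    increment = max(0.0, scenario_intake - baseline_intake)
    return dose.rr_per_200g ** (increment / dose.reference_dose)
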