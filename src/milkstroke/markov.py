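"""Four-state Markov cohort engine.

A closed cohort is split at baseline into "healthy" (never had a
stroke) and "chronic" (stroke survivors, by prevalence) and propagated
through annual cycles.  Two absorbing states collect stroke deaths and
deaths from other causes.  Transitions are irreversible: nobody returns
from chronic to healthy, and the 28-day acute-phase fatality of a
stroke event is folded into the transition at onset rather than
modelled as a separate state.

Per cycle, with ``p_inc`` the (relative-risk-adjusted) first-ever
stroke probability, ``f`` the 28-day case fatality, ``r_eff`` the
(relative-risk-adjusted) recurrence probability and ``p_oth`` the
other-cause death probability:

* healthy  -> chronic:       ``p_inc * (1 - f)``
* healthy  -> death_stroke:  ``p_inc * f``
* healthy  -> death_other:   ``p_oth``
* chronic  -> death_stroke:  ``r_eff * f``   (nonfatal recurrences stay chronic)
* chronic  -> death_other:   ``p_oth``

The milk dose-response applies to every stroke event — first-ever and
recurrent alike — since the protective exposure does not cease after a
first stroke.  Headline "stroke cases" and "stroke-related deaths"
nevertheless count first-ever events only; recurrent events and their
acute deaths are tallied separately because they drive inpatient costs
and the chronic-pool dynamics.

Published rates per 100,000 person-years are small (< 3,000), so they
convert to annual probabilities by direct division by 100,000; the
``1 - exp(-rate)`` refinement would differ by under 0.05%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelConfig, DoseResponse, SexLevelParameters, Stratum, StratumParameters
from .scenarios import ScenarioName, ScenarioSpec, build_trajectory, effective_relative_risk

__all__ = [
    "StateVector",
    "TransitionMatrix",
    "CycleTally",
    "CohortTrajectory",
    "rate_to_probability",
    "initial_state",
    "build_transition_matrix",
    "step",
    "run_cohort",
]

#: State indices of the transition matrix.
HEALTHY, CHRONIC, DEATH_STROKE, DEATH_OTHER = range(4)


@dataclass(frozen=True)
class StateVector:
    """Expected state occupancies (persons) at one point in time."""

    healthy: float
    chronic: float
    death_stroke: float = 0.0
    death_other: float = 0.0

    @property
    def total(self) -> float:
        return self.healthy + self.chronic + self.death_stroke + self.death_other

    def as_array(self) -> np.ndarray:
        return np.array([self.healthy, self.chronic, self.death_stroke, self.death_other])


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 annual transition probabilities plus the event
    probabilities needed to tally cases within a cycle."""

    matrix: np.ndarray
    p_incidence: float  # healthy -> any stroke event (RR-adjusted)
    p_recurrence: float  # chronic -> recurrent event (RR-adjusted)
    fatality: float
    p_other_death: float


@dataclass(frozen=True)
class CycleTally:
    """Event counts for one cycle.

    ``first_events`` counts all first-ever strokes (fatal and nonfatal);
    acute deaths are the fatality share of the corresponding events.
    """

    first_events: float
    first_event_acute_deaths: float
    recurrent_events: float
    recurrent_acute_deaths: float
    other_deaths: float


@dataclass(frozen=True)
class CohortTrajectory:
    """One stratum propagated through the full horizon under one scenario."""

    stratum: Stratum
    scenario: ScenarioName
    occupancy_by_cycle: tuple[StateVector, ...]  # length horizon + 1, incl. initial
    tallies_by_cycle: tuple[CycleTally, ...]  # length horizon

    @property
    def cumulative_first_events(self) -> float:
        return sum(t.first_events for t in self.tallies_by_cycle)

    @property
    def cumulative_first_event_deaths(self) -> float:
        return sum(t.first_event_acute_deaths for t in self.tallies_by_cycle)

    @property
    def cumulative_recurrent_events(self) -> float:
        return sum(t.recurrent_events for t in self.tallies_by_cycle)


def rate_to_probability(rate: float) -> float:
    """Annual probability from a rate per 100,000 person-years, capped at 1."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return min(rate / 100_000.0, 1.0)


def initial_state(params: StratumParameters) -> StateVector:
    """Split the stratum population by stroke prevalence; death states start empty."""
    chronic = params.population * rate_to_probability(params.prevalence.point)
    return StateVector(healthy=params.population - chronic, chronic=chronic)


def build_transition_matrix(
    params: StratumParameters,
    sex_params: SexLevelParameters,
    rr_effective: float = 1.0,
) -> TransitionMatrix:
    """Annual transition matrix for one stratum at a given effective relative risk.

    ``rr_effective`` multiplies both the first-ever incidence and the
    recurrence probability.  Raises if any row remainder would be
    negative (possible only with user-supplied extreme inputs; such rows
    are rejected rather than renormalised).
    """
    if not rr_effective > 0:
        raise ValueError(f"rr_effective must be > 0, got {rr_effective}")
    p_inc = min(rate_to_probability(params.incidence.point) * rr_effective, 1.0)
    p_oth = rate_to_probability(
        params.all_cause_mortality.point - params.stroke_mortality.point
    )
    f = sex_params.fatality_28day
    r_eff = min(sex_params.recurrence_rate * rr_effective, 1.0)

    healthy_stay = 1.0 - p_inc - p_oth
    chronic_stay = 1.0 - r_eff * f - p_oth
    if healthy_stay < 0 or chronic_stay < 0:
        raise ValueError(
            f"{params.stratum.label}: transition probabilities exceed 1 "
            f"(healthy remainder {healthy_stay:.6f}, chronic remainder {chronic_stay:.6f}; "
            f"p_inc={p_inc:.6f}, p_oth={p_oth:.6f}, r*f={r_eff * f:.6f})"
        )
    m = np.array(
        [
            [healthy_stay, p_inc * (1 - f), p_inc * f, p_oth],
            [0.0, chronic_stay, r_eff * f, p_oth],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(
        matrix=m,
        p_incidence=p_inc,
        p_recurrence=r_eff,
        fatality=f,
        p_other_death=p_oth,
    )


def step(state: StateVector, tm: TransitionMatrix) -> tuple[StateVector, CycleTally]:
    """Advance the cohort one cycle and tally the events it generates."""
    new = state.as_array() @ tm.matrix
    first = state.healthy * tm.p_incidence
    recurrent = state.chronic * tm.p_recurrence
    tally = CycleTally(
        first_events=first,
        first_event_acute_deaths=first * tm.fatality,
        recurrent_events=recurrent,
        recurrent_acute_deaths=recurrent * tm.fatality,
        other_deaths=(state.healthy + state.chronic) * tm.p_other_death,
    )
    return StateVector(*new), tally


def run_cohort(
    params: StratumParameters,
    sex_params: SexLevelParameters,
    dose: DoseResponse,
    spec: ScenarioSpec,
    config: ModelConfig,
) -> CohortTrajectory:
    """Propagate one stratum through the horizon under a scenario.

    Each cycle uses that cycle's effective relative risk from the
    scenario's intake trajectory.  Cumulative reported "stroke cases"
    are the summed first-ever events; "stroke-related deaths" are the
    28-day acute deaths among those events.
    """
    traj = build_trajectory(spec, params, config)
    state = initial_state(params)
    occupancy = [state]
    tallies: list[CycleTally] = []
    for intake in traj.intake_by_cycle:
        rr = effective_relative_risk(dose, params.dairy_intake_mean, intake)
        tm = build_transition_matrix(params, sex_params, rr)
        state, tally = step(state, tm)
        occupancy.append(state)
        tallies.append(tally)
    return CohortTrajectory(
        stratum=params.stratum,
        scenario=spec.name,
        occupancy_by_cycle=tuple(occupancy),
        tallies_by_cycle=tuple(tallies),
    )
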