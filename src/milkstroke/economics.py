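"""Healthcare expenditure: unit-cost calibration, accrual, discounting.

Published expenditure data are annual national aggregates per stratum
(inpatient care, outpatient care, prescription drugs; USD).  The model
turns them into unit costs by anchoring the base-case first simulation
year to those aggregates:

* inpatient cost per stroke event = annual inpatient aggregate divided
  by the base-case cycle-1 event count (first-ever plus recurrent, since
  every onset admits);
* chronic-state cost per person-year (outpatient + drugs) = the summed
  aggregates divided by the base-case end-of-cycle-1 chronic occupancy.

By construction the undiscounted base-case cycle-1 expenditure then
equals the stratum's published annual total exactly.  Future costs are
discounted at a fixed annual rate with the first year undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .markov import CohortTrajectory
from .parameters import CostParameters, ModelConfig, Sex, Stratum
from .scenarios import ScenarioName

__all__ = [
    "UnitCosts",
    "ExpenditureResult",
    "calibrate_unit_costs",
    "discount_factor",
    "accrue_costs",
    "compare_scenarios",
    "milk_retail_price",
    "estimate_purchase_cost",
]


@dataclass(frozen=True)
class UnitCosts:
    stratum: Stratum
    inpatient_per_event: float
    chronic_per_person_year: float


@dataclass(frozen=True)
class ExpenditureResult:
    """Discounted per-cycle and cumulative stroke expenditure (USD)."""

    stratum: Stratum
    scenario: ScenarioName
    cost_by_cycle: tuple[float, ...]

    @property
    def cumulative_cost(self) -> float:
        return sum(self.cost_by_cycle)


def calibrate_unit_costs(
    costs: CostParameters, base_trajectory: CohortTrajectory
) -> UnitCosts:
    """Unit costs that anchor base-case year-1 spending to the annual aggregates."""
    if base_trajectory.scenario is not ScenarioName.BASE_CASE:
        raise ValueError("unit costs must be calibrated against a base-case trajectory")
    if costs.stratum != base_trajectory.stratum:
        raise ValueError(
            f"stratum mismatch: costs {costs.stratum.label} vs "
            f"trajectory {base_trajectory.stratum.label}"
        )
    tally1 = base_trajectory.tallies_by_cycle[0]
    events1 = tally1.first_events + tally1.recurrent_events
    chronic1 = base_trajectory.occupancy_by_cycle[1].chronic

    if costs.inpatient_annual == 0:
        inpatient = 0.0
    elif events1 <= 0:
        raise ValueError(f"{costs.stratum.label}: no cycle-1 events to allocate inpatient costs")
    else:
        inpatient = costs.inpatient_annual / events1

    ambulatory = costs.outpatient_annual + costs.drug_annual
    if ambulatory == 0:
        chronic_cost = 0.0
    elif chronic1 <= 0:
        raise ValueError(f"{costs.stratum.label}: empty chronic pool, cannot allocate costs")
    else:
        chronic_cost = ambulatory / chronic1
    return UnitCosts(costs.stratum, inpatient, chronic_cost)


def discount_factor(cycle_index: int, rate: float) -> float:
    """Present-value factor for 0-based ``cycle_index``; the first year is undiscounted."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-cycle_index)


def accrue_costs(
    trajectory: CohortTrajectory, unit_costs: UnitCosts, config: ModelConfig
) -> ExpenditureResult:
    """Discounted stroke expenditure per cycle for one stratum/scenario.

    Inpatient costs follow every stroke event (first-ever and
    recurrent); chronic-state costs follow end-of-cycle chronic
    occupancy.
    """
    if trajectory.stratum != unit_costs.stratum:
        raise ValueError(
            f"stratum mismatch: trajectory {trajectory.stratum.label} vs "
            f"unit costs {unit_costs.stratum.label}"
        )
    per_cycle = []
    for k, tally in enumerate(trajectory.tallies_by_cycle):
        events = tally.first_events + tally.recurrent_events
        chronic_end = trajectory.occupancy_by_cycle[k + 1].chronic
        undiscounted = (
            events * unit_costs.inpatient_per_event
            + chronic_end * unit_costs.chronic_per_person_year
        )
        per_cycle.append(undiscounted * discount_factor(k, config.discount_rate))
    return ExpenditureResult(
        stratum=trajectory.stratum,
        scenario=trajectory.scenario,
        cost_by_cycle=tuple(per_cycle),
    )


def compare_scenarios(
    base: Mapping[Stratum, ExpenditureResult],
    intervention: Mapping[Stratum, ExpenditureResult],
) -> pd.DataFrame:
    """Savings table (absolute USD and percent) per stratum, per sex, and overall.

    Aggregates sum the absolute values and recompute percentages.
    """
    if set(base) != set(intervention):
        raise ValueError("base and intervention cover different strata")
    rows = []
    for stratum in sorted(base, key=lambda s: (s.sex.value, s.age_band)):
        b = base[stratum].cumulative_cost
        i = intervention[stratum].cumulative_cost
        rows.append(
            {
                "sex": stratum.sex.value,
                "age_band": stratum.age_band,
                "base_usd": b,
                "intervention_usd": i,
                "savings_usd": b - i,
            }
        )
    table = pd.DataFrame(rows)
    totals = []
    for sex in (Sex.MEN.value, Sex.WOMEN.value):
        sub = table[table["sex"] == sex]
        totals.append(
            {
                "sex": sex,
                "age_band": "30-79",
                "base_usd": sub["base_usd"].sum(),
                "intervention_usd": sub["intervention_usd"].sum(),
                "savings_usd": sub["savings_usd"].sum(),
            }
        )
    totals.append(
        {
            "sex": "both",
            "age_band": "30-79",
            "base_usd": table["base_usd"].sum(),
            "intervention_usd": table["intervention_usd"].sum(),
            "savings_usd": table["savings_usd"].sum(),
        }
    )
    table = pd.concat([table, pd.DataFrame(totals)], ignore_index=True)
    table["savings_pct"] = 100.0 * table["savings_usd"] / table["base_usd"]
    return table


def milk_retail_price(
    total_sales_usd: float, shipment_volume_kl: float, density_g_per_ml: float = 1.03
) -> float:
    """Average retail price of milk in USD per 100 g, from annual sales and shipments."""
    grams = shipment_volume_kl * 1e6 * density_g_per_ml  # kL -> mL -> g
    return total_sales_usd / (grams / 100.0)


def estimate_purchase_cost(
    price_per_100g: float, baseline_intake: float, target_intake: float
) -> float:
    """Extra daily milk spending (USD/person/day) to move from baseline to target intake."""
    return price_per_100g * max(0.0, target_intake - baseline_intake) / 100.0
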