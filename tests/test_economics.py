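"""Cost calibration, accrual, discounting, and the milk-price helpers."""

import dataclasses

import pytest

from milkstroke.economics import (
    accrue_costs,
    calibrate_unit_costs,
    compare_scenarios,
    discount_factor,
    estimate_purchase_cost,
    milk_retail_price,
)
from milkstroke.parameters import CostParameters, Sex, Stratum
from milkstroke.scenarios import ScenarioName

MEN_OLD = Stratum(Sex.MEN, "70-79")


class TestDiscounting:
    def test_first_year_undiscounted(self):
        assert discount_factor(0, 0.02) == 1.0

    def test_tenth_year_factor(self):
        assert discount_factor(9, 0.02) == pytest.approx(1.02 ** -9, rel=1e-12)
        assert discount_factor(9, 0.02) == pytest.approx(0.83676, abs=5e-6)

    def test_geometric_series_sum(self):
        total = sum(discount_factor(k, 0.02) for k in range(10))
        # closed-form geometric oracle
        assert total == pytest.approx((1 - 1.02 ** -10) / (1 - 1.02 ** -1), rel=1e-12)
        assert total == pytest.approx(9.16224, abs=5e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestCalibration:
    def test_inpatient_cost_per_event_oldest_men(self, paper, result):
        unit = result.unit_costs[MEN_OLD]
        tally1 = result.base.trajectories[MEN_OLD].tallies_by_cycle[0]
        events1 = tally1.first_events + tally1.recurrent_events
        assert unit.inpatient_per_event == pytest.approx(1_282_319_379 / events1, rel=1e-12)
        assert unit.inpatient_per_event == pytest.approx(5957, abs=10)

    def test_chronic_cost_per_person_year_oldest_men(self, paper, result):
        unit = result.unit_costs[MEN_OLD]
        chronic1 = result.base.trajectories[MEN_OLD].occupancy_by_cycle[1].chronic
        expected = (219_073_369 + 170_304_477) / chronic1
        assert unit.chronic_per_person_year == pytest.approx(expected, rel=1e-12)
        assert unit.chronic_per_person_year == pytest.approx(625, abs=10)

    def test_base_case_cycle1_cost_equals_published_annual_total(self, paper, result):
        """The calibration anchors undiscounted year-1 spending to the aggregates."""
        for stratum, cost in paper.costs.items():
            published = cost.inpatient_annual + cost.outpatient_annual + cost.drug_annual
            cycle1 = result.base.expenditures[stratum].cost_by_cycle[0]
            assert cycle1 == pytest.approx(published, rel=1e-9)  # factor at k=0 is 1

    def test_zero_aggregates_give_zero_unit_costs(self, paper, result):
        zero = CostParameters(MEN_OLD, 0.0, 0.0, 0.0)
        unit = calibrate_unit_costs(zero, result.base.trajectories[MEN_OLD])
        assert unit.inpatient_per_event == 0.0
        assert unit.chronic_per_person_year == 0.0

    def test_calibration_requires_base_case(self, paper, result):
        s1 = result[ScenarioName.SCENARIO_1].trajectories[MEN_OLD]
        with pytest.raises(ValueError, match="base-case"):
            calibrate_unit_costs(paper.costs[MEN_OLD], s1)


class TestAccrual:
    def test_cumulative_is_sum_of_cycles(self, result):
        for exp in result.base.expenditures.values():
            assert exp.cumulative_cost == pytest.approx(sum(exp.cost_by_cycle), rel=1e-12)
            assert all(c >= 0 for c in exp.cost_by_cycle)

    def test_linear_in_unit_costs(self, paper, result):
        traj = result.base.trajectories[MEN_OLD]
        unit = result.unit_costs[MEN_OLD]
        doubled = dataclasses.replace(
            unit,
            inpatient_per_event=2 * unit.inpatient_per_event,
            chronic_per_person_year=2 * unit.chronic_per_person_year,
        )
        a = accrue_costs(traj, unit, paper.config).cumulative_cost
        b = accrue_costs(traj, doubled, paper.config).cumulative_cost
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_stratum_mismatch_rejected(self, paper, result):
        other = result.unit_costs[Stratum(Sex.WOMEN, "30-39")]
        with pytest.raises(ValueError, match="mismatch"):
            accrue_costs(result.base.trajectories[MEN_OLD], other, paper.config)

    def test_discounted_total_strictly_decreasing_in_rate(self, paper, result):
        traj = result.base.trajectories[MEN_OLD]
        unit = result.unit_costs[MEN_OLD]
        totals = [
            accrue_costs(traj, unit, dataclasses.replace(paper.config, discount_rate=r))
            .cumulative_cost
            for r in (0.0, 0.01, 0.02, 0.04)
        ]
        assert all(b < a for a, b in zip(totals, totals[1:]))


class TestComparison:
    def test_identical_runs_give_zero_savings(self, result):
        table = compare_scenarios(result.base.expenditures, result.base.expenditures)
        assert (table["savings_usd"] == 0).all()
        assert (table["savings_pct"] == 0).all()

    def test_savings_non_negative_and_aggregated(self, result):
        s1 = result[ScenarioName.SCENARIO_1]
        table = compare_scenarios(result.base.expenditures, s1.expenditures)
        assert (table["savings_usd"] >= 0).all()
        both = table[(table["sex"] == "both")].iloc[0]
        strata_rows = table[table["age_band"] != "30-79"]
        assert both["savings_usd"] == pytest.approx(strata_rows["savings_usd"].sum())
        assert both["savings_pct"] == pytest.approx(
            100 * both["savings_usd"] / both["base_usd"]
        )

    def test_mismatched_strata_rejected(self, result):
        partial = {
            s: e for s, e in result.base.expenditures.items() if s.sex == Sex.MEN
        }
        with pytest.raises(ValueError, match="strata"):
            compare_scenarios(result.base.expenditures, partial)


class TestMilkPrice:
    def test_retail_price_from_sales_and_shipments(self):
        price = milk_retail_price(3.86e9, 3_211_400, 1.03)
        assert price == pytest.approx(0.1167, abs=5e-4)
        assert round(price, 2) == 0.12

    def test_purchase_cost_for_typical_gap(self):
        price = milk_retail_price(3.86e9, 3_211_400, 1.03)
        assert estimate_purchase_cost(price, 136.7, 180.0) == pytest.approx(0.05, abs=0.005)

    def test_no_gap_costs_nothing(self):
        assert estimate_purchase_cost(0.12, 180.0, 180.0) == 0.0
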