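"""Markov engine: matrices, propagation, tallies, conservation."""

import dataclasses

import numpy as np
import pytest

from milkstroke.markov import (
    StateVector,
    build_transition_matrix,
    initial_state,
    rate_to_probability,
    run_cohort,
    step,
)
from milkstroke.parameters import RateWithCI, Sex, SexLevelParameters, Stratum
from milkstroke.scenarios import BASE_CASE, SCENARIO_1, SCENARIO_2, ScenarioName

MEN_OLD = Stratum(Sex.MEN, "70-79")


class TestRateConversion:
    @pytest.mark.parametrize("rate, expected", [(560.9, 0.005609), (0.0, 0.0), (2708.6, 0.027086)])
    def test_divides_by_100k(self, rate, expected):
        assert rate_to_probability(rate) == pytest.approx(expected, rel=1e-12)

    def test_caps_at_one(self):
        assert rate_to_probability(2e5) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-1.0)


class TestInitialState:
    def test_prevalence_split_oldest_men(self, paper):
        state = initial_state(paper.strata[MEN_OLD])
        assert state.chronic == pytest.approx(7_438_000 * 0.084413, rel=1e-12)
        assert state.chronic == pytest.approx(627_864, abs=1.0)
        assert state.healthy == pytest.approx(6_810_136, abs=1.0)
        assert state.death_stroke == 0.0 and state.death_other == 0.0

    def test_prevalence_split_young_women(self, paper):
        state = initial_state(paper.strata[Stratum(Sex.WOMEN, "30-39")])
        assert state.chronic == pytest.approx(6_469_000 * 0.004433, rel=1e-12)
        assert state.chronic == pytest.approx(28_677, abs=1.0)

    def test_zero_prevalence_means_everyone_healthy(self, paper):
        p = dataclasses.replace(
            paper.strata[MEN_OLD], prevalence=RateWithCI(0.0, 0.0, 0.0)
        )
        state = initial_state(p)
        assert state.healthy == p.population and state.chronic == 0.0


class TestTransitionMatrix:
    def test_healthy_row_oldest_men(self, paper):
        tm = build_transition_matrix(paper.strata[MEN_OLD], paper.sex_level[Sex.MEN])
        row = tm.matrix[0]
        assert row[0] == pytest.approx(0.969573, abs=1e-6)
        assert row[1] == pytest.approx(0.004773, abs=1e-6)
        assert row[2] == pytest.approx(0.000836, abs=1e-6)
        assert row[3] == pytest.approx(0.024818, abs=1e-9)

    def test_chronic_fatal_recurrence_is_product_of_scalars(self, paper):
        tm = build_transition_matrix(paper.strata[MEN_OLD], paper.sex_level[Sex.MEN])
        assert tm.matrix[1, 2] == pytest.approx(0.282 * 0.149, rel=1e-12)

    def test_all_rows_stochastic_and_death_rows_absorbing(self, paper):
        for stratum, p in paper.strata.items():
            for rr in (1.0, 0.9087, 0.75):
                tm = build_transition_matrix(p, paper.sex_level[stratum.sex], rr)
                assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-12)
                assert (tm.matrix >= 0).all() and (tm.matrix <= 1).all()
                assert tm.matrix[2].tolist() == [0, 0, 1, 0]
                assert tm.matrix[3].tolist() == [0, 0, 0, 1]
                assert tm.matrix[1, 0] == 0.0  # irreversible: no chronic -> healthy

    def test_relative_risk_scales_incidence_and_recurrence(self, paper):
        p = paper.strata[MEN_OLD]
        tm = build_transition_matrix(p, paper.sex_level[Sex.MEN], rr_effective=0.9)
        assert tm.p_incidence == pytest.approx(0.005609 * 0.9, rel=1e-12)
        assert tm.p_recurrence == pytest.approx(0.282 * 0.9, rel=1e-12)

    def test_zero_rates_give_identity(self, paper):
        zero = RateWithCI(0.0, 0.0, 0.0)
        p = dataclasses.replace(
            paper.strata[MEN_OLD],
            incidence=zero,
            stroke_mortality=zero,
            all_cause_mortality=zero,
        )
        sex = SexLevelParameters(fatality_28day=0.149, recurrence_rate=1e-300)
        tm = build_transition_matrix(p, sex)
        assert np.allclose(tm.matrix, np.eye(4), atol=1e-12)

    def test_overfull_row_fails_loudly(self, paper):
        p = dataclasses.replace(
            paper.strata[MEN_OLD],
            incidence=RateWithCI(60_000.0, 60_000.0, 60_000.0),
            all_cause_mortality=RateWithCI(99_000.0, 99_000.0, 99_000.0),
        )
        with pytest.raises(ValueError, match="men 70-79"):
            build_transition_matrix(p, paper.sex_level[Sex.MEN])


class TestStep:
    def test_identity_matrix_leaves_state_unchanged(self, paper):
        p = paper.strata[MEN_OLD]
        zero = RateWithCI(0.0, 0.0, 0.0)
        quiet = dataclasses.replace(
            p, incidence=zero, stroke_mortality=zero, all_cause_mortality=zero
        )
        tm = build_transition_matrix(
            quiet, SexLevelParameters(fatality_28day=0.5, recurrence_rate=1e-300)
        )
        state = StateVector(healthy=100.0, chronic=50.0)
        new, tally = step(state, tm)
        np.testing.assert_allclose(new.as_array(), state.as_array(), rtol=1e-12, atol=1e-290)
        assert tally.first_events == 0.0
        assert tally.recurrent_events == pytest.approx(0.0, abs=1e-290)

    def test_first_cycle_event_counts_oldest_men(self, paper):
        p = paper.strata[MEN_OLD]
        tm = build_transition_matrix(p, paper.sex_level[Sex.MEN])
        _, tally = step(initial_state(p), tm)
        assert tally.first_events == pytest.approx(6_810_136 * 0.005609, rel=1e-4)
        assert tally.recurrent_events == pytest.approx(627_864 * 0.282, rel=1e-4)
        assert tally.first_event_acute_deaths == pytest.approx(
            tally.first_events * 0.149, rel=1e-12
        )
        assert tally.recurrent_acute_deaths == pytest.approx(
            tally.recurrent_events * 0.149, rel=1e-12
        )


class TestRunCohort:
    def test_conservation_at_every_cycle(self, paper):
        for stratum, p in paper.strata.items():
            traj = run_cohort(
                p, paper.sex_level[stratum.sex], paper.dose, SCENARIO_2, paper.config
            )
            for state in traj.occupancy_by_cycle:
                assert state.total == pytest.approx(p.population, abs=1e-6)
            healthy = [s.healthy for s in traj.occupancy_by_cycle]
            assert all(b <= a for a, b in zip(healthy, healthy[1:]))

    def test_matrix_power_oracle_for_constant_rr(self, paper):
        """States under a constant-intake scenario equal v0 @ M^k."""
        for spec in (BASE_CASE, SCENARIO_1):
            for stratum in (MEN_OLD, Stratum(Sex.WOMEN, "40-49")):
                p = paper.strata[stratum]
                traj = run_cohort(
                    p, paper.sex_level[stratum.sex], paper.dose, spec, paper.config
                )
                intake = p.dairy_intake_mean if spec is BASE_CASE else 180.0
                rr = paper.dose.rr_per_200g ** (
                    max(0.0, intake - p.dairy_intake_mean) / 200.0
                )
                m = build_transition_matrix(p, paper.sex_level[stratum.sex], rr).matrix
                v0 = traj.occupancy_by_cycle[0].as_array()
                for k, state in enumerate(traj.occupancy_by_cycle):
                    expected = v0 @ np.linalg.matrix_power(m, k)
                    np.testing.assert_allclose(state.as_array(), expected, rtol=1e-9)

    def test_null_dose_response_reproduces_base_case(self, paper):
        null = dataclasses.replace(paper.dose, rr_per_200g=1.0, ci_lower=1.0, ci_upper=1.0)
        p = paper.strata[MEN_OLD]
        base = run_cohort(p, paper.sex_level[Sex.MEN], null, BASE_CASE, paper.config)
        s1 = run_cohort(p, paper.sex_level[Sex.MEN], null, SCENARIO_1, paper.config)
        for a, b in zip(base.occupancy_by_cycle, s1.occupancy_by_cycle):
            np.testing.assert_allclose(a.as_array(), b.as_array(), rtol=1e-12)
        assert base.cumulative_first_events == pytest.approx(s1.cumulative_first_events)

    def test_reported_deaths_are_fatality_times_cases(self, result):
        """Sex-specific 28-day fatality ties cumulative deaths to cases exactly."""
        for sex, fatality in ((Sex.MEN, 0.149), (Sex.WOMEN, 0.157)):
            cases = result.base.cumulative_cases(sex)
            deaths = result.base.cumulative_deaths(sex)
            assert deaths / cases == pytest.approx(fatality, rel=1e-12)

    def test_prevented_events_ordering_s1_s2(self, result):
        """Immediate uptake prevents at least as much as gradual, per stratum."""
        base = result.base
        s1 = result[ScenarioName.SCENARIO_1]
        s2 = result[ScenarioName.SCENARIO_2]
        for stratum in base.trajectories:
            b = base.trajectories[stratum].cumulative_first_events
            p1 = b - s1.trajectories[stratum].cumulative_first_events
            p2 = b - s2.trajectories[stratum].cumulative_first_events
            assert p1 >= p2 >= 0.0

    def test_cases_monotone_in_target_intake(self, paper):
        """Raising the milk target never increases cumulative first events."""
        p = paper.strata[MEN_OLD]
        previous = None
        for target in (p.dairy_intake_mean, 140.0, 160.0, 180.0):
            spec = dataclasses.replace(SCENARIO_1, target_intake=target)
            traj = run_cohort(p, paper.sex_level[Sex.MEN], paper.dose, spec, paper.config)
            cases = traj.cumulative_first_events
            if previous is not None:
                assert cases <= previous
            previous = cases
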