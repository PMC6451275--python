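"""Attendance simulation against its closed-form discretized-normal oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anc_cea.attendance import (
    AttendanceScenario,
    draw_visit_counts,
    expected_cost_closed_form,
    relative_spread_check,
    simulate_cost_distribution,
    visit_count_pmf,
)
from anc_cea.schedules import VisitCostSchedule


class TestDrawVisitCounts:
    def test_degenerate_scenario_is_constant(self):
        scenario = AttendanceScenario("full", 4, 0.0, 4, 4, degenerate=True)
        counts = draw_visit_counts(scenario, 10, seed=0)
        assert counts.tolist() == [4] * 10

    def test_large_cohort_mean_near_scenario_mean(self, scenarios):
        # 3*SE = 3*0.8/sqrt(373679) ~ 0.004
        counts = draw_visit_counts(scenarios["scenario-1"], 373_679, seed=7)
        assert counts.mean() == pytest.approx(5.0, abs=0.004)

    def test_range_limits_reached_in_large_cohort(self, scenarios):
        counts = draw_visit_counts(scenarios["scenario-1"], 373_679, seed=7)
        assert counts.min() == 1 and counts.max() == 8

    def test_counts_always_within_bounds(self, scenarios):
        for sc in scenarios.values():
            counts = draw_visit_counts(sc, 10_000, seed=3)
            assert counts.min() >= sc.min_visits
            assert counts.max() <= sc.max_visits

    def test_reproducible_for_fixed_seed(self, scenarios):
        a = draw_visit_counts(scenarios["scenario-2"], 1000, seed=11)
        b = draw_visit_counts(scenarios["scenario-2"], 1000, seed=11)
        assert np.array_equal(a, b)

    def test_rejects_empty_cohort(self, scenarios):
        with pytest.raises(ValueError):
            draw_visit_counts(scenarios["scenario-1"], 0, seed=0)


class TestClosedFormOracle:
    def test_pmf_sums_to_one(self, scenarios):
        for sc in scenarios.values():
            _, probs = visit_count_pmf(sc)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scenario1_expected_cost(self, eight_visit, scenarios):
        # hand evaluation of the discretized-normal sum over k=1..8
        mean, sd = expected_cost_closed_form(eight_visit, scenarios["scenario-1"])
        assert mean == pytest.approx(53.06, abs=0.01)
        assert sd == pytest.approx(6.62, abs=0.01)

    def test_scenario2_expected_cost_rounds_to_61(self, eight_visit, scenarios):
        mean, _ = expected_cost_closed_form(eight_visit, scenarios["scenario-2"])
        assert round(mean) == 61

    def test_degenerate_point_mass(self, eight_visit):
        scenario = AttendanceScenario("five", 5, 0.0, 5, 5, degenerate=True)
        mean, sd = expected_cost_closed_form(eight_visit, scenario)
        assert mean == 52.0 and sd == 0.0


class TestSimulation:
    def test_mean_matches_oracle_within_3_mc_se(self, eight_visit, scenarios):
        sc = scenarios["scenario-1"]
        result = simulate_cost_distribution(eight_visit, sc, 20_000, 20, seed=5)
        mean, sd = expected_cost_closed_form(eight_visit, sc)
        se_total = sd * math.sqrt(20_000) / math.sqrt(20)
        assert abs(result.mean_total - 20_000 * mean) <= 3 * se_total

    def test_per_woman_sd_matches_oracle(self, eight_visit, scenarios):
        sc = scenarios["scenario-2"]
        result = simulate_cost_distribution(eight_visit, sc, 50_000, 5, seed=5)
        _, sd = expected_cost_closed_form(eight_visit, sc)
        assert result.sd_cost_per_woman == pytest.approx(sd, rel=0.02)

    def test_fixed_seed_bit_identical_totals(self, eight_visit, scenarios):
        sc = scenarios["scenario-1"]
        r1 = simulate_cost_distribution(eight_visit, sc, 5000, 10, seed=42)
        r2 = simulate_cost_distribution(eight_visit, sc, 5000, 10, seed=42)
        assert np.array_equal(r1.total_cost_per_replication, r2.total_cost_per_replication)

    def test_expected_cost_monotone_in_mean_visits(self, eight_visit):
        means = [
            expected_cost_closed_form(
                eight_visit, AttendanceScenario("m", mu, 0.8, 1, 11)
            )[0]
            for mu in (3, 4, 5, 6, 7, 8)
        ]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_summary_invariants(self, eight_visit, scenarios):
        r = simulate_cost_distribution(
            eight_visit, scenarios["scenario-3"], 2000, 30, seed=9
        )
        assert r.min_total <= r.mean_total <= r.max_total
        assert r.relative_spread >= 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    costs=st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=10),
    mu=st.floats(min_value=2.0, max_value=8.0),
    sigma=st.floats(min_value=0.3, max_value=2.0),
    data=st.data(),
)
def test_simulation_converges_to_oracle_for_random_designs(costs, mu, sigma, data):
    """Property: for arbitrary schedules and attendance scenarios, the
    simulated mean total stays within 3 Monte-Carlo SE of the analytic
    expectation."""
    lo = data.draw(st.integers(min_value=1, max_value=int(mu)))
    hi = data.draw(st.integers(min_value=max(int(mu) + 1, lo + 1), max_value=14))
    schedule = VisitCostSchedule("rand", tuple(costs), 6.0)
    scenario = AttendanceScenario("rand", mu, sigma, lo, hi)
    cohort, reps = 4000, 8
    result = simulate_cost_distribution(schedule, scenario, cohort, reps, seed=1234)
    mean, sd = expected_cost_closed_form(schedule, scenario)
    se_total = sd * math.sqrt(cohort / reps)
    assert abs(result.mean_total - cohort * mean) <= 3 * se_total + 1e-9


class TestRelativeSpread:
    def test_published_style_totals(self):
        # arithmetic on a min/max/mean triple: (max-min)/mean
        r = simulate_cost_distribution(
            VisitCostSchedule("s", (1,)),
            AttendanceScenario("d", 1, 0.0, 1, 1, degenerate=True),
            10,
            2,
            seed=0,
        )
        r.mean_total, r.min_total, r.max_total = 19_829_260.0, 19_818_549.0, 19_837_028.0
        r.relative_spread = (r.max_total - r.min_total) / r.mean_total
        ok, spread = relative_spread_check(r, threshold=0.002)
        assert ok and spread == pytest.approx(9.3e-4, rel=0.01)

    def test_constant_replications_have_zero_spread(self):
        scenario = AttendanceScenario("full", 4, 0.0, 4, 4, degenerate=True)
        r = simulate_cost_distribution(
            VisitCostSchedule("four", (21, 6, 6, 11)), scenario, 100, 5, seed=0
        )
        ok, spread = relative_spread_check(r)
        assert ok and spread == 0.0

    def test_requires_two_replications(self, eight_visit, scenarios):
        r = simulate_cost_distribution(
            eight_visit, scenarios["scenario-1"], 100, 1, seed=0
        )
        with pytest.raises(ValueError):
            relative_spread_check(r)
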