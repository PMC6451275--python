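"""Deaths averted, annuity discounting and life-years saved."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anc_cea.elicitation import OutcomeScenario
from anc_cea.outcomes import (
    BaselineEpidemiology,
    annuity_factor,
    deaths_averted,
    health_gains,
    maternal_lys,
    maternal_years_per_death,
    perinatal_lys,
)


def _baseline(**overrides):
    defaults = dict(
        annual_perinatal_deaths=10_076,
        annual_maternal_deaths=371,
        discount_rate=0.03,
        perinatal_discount_horizon_years=66,
        maternal_age_distribution=((30.0, 1.0),),
    )
    defaults.update(overrides)
    return BaselineEpidemiology(**defaults)


class TestDeathsAverted:
    @pytest.mark.parametrize(
        "baseline, pct, expected",
        [
            (10_076, 22.5, 2267),
            (10_076, 55.0, 5542),
            (371, 7.0, 26),
            (371, 52.5, 195),
            (500, 0.0, 0),
        ],
    )
    def test_reference_values(self, baseline, pct, expected):
        assert deaths_averted(baseline, pct) == expected

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            deaths_averted(-1, 10)
        with pytest.raises(ValueError):
            deaths_averted(100, 150)

    @settings(deadline=None)
    @given(
        deaths=st.integers(min_value=0, max_value=100_000),
        pct=st.floats(min_value=0, max_value=100),
    )
    def test_bounded_by_baseline_and_monotone(self, deaths, pct):
        averted = deaths_averted(deaths, pct)
        assert 0 <= averted <= deaths
        assert averted >= deaths_averted(deaths, pct / 2)


class TestAnnuityFactor:
    def test_zero_rate_equals_horizon(self):
        assert annuity_factor(36, 0.0) == 36.0

    @pytest.mark.parametrize(
        "horizon, expected",
        [(64, 28.3065), (66, 28.5950), (36, 21.8323)],
    )
    def test_closed_form_values(self, horizon, expected):
        assert annuity_factor(horizon, 0.03) == pytest.approx(expected, abs=5e-4)

    @settings(deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=80),
        r=st.floats(min_value=1e-6, max_value=0.2),
    )
    def test_below_horizon_and_monotone(self, n, r):
        # rate/horizon bounded so the year-n+1 increment stays above
        # machine precision and strict inequalities are meaningful
        a = annuity_factor(n, r)
        assert a < n
        assert a < annuity_factor(n + 1, r)
        assert a > annuity_factor(n, r + 0.01)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            annuity_factor(10, -0.01)


class TestPerinatalLys:
    def test_pessimistic_reference_value(self):
        # 2267 averted deaths over a 66-year horizon at 3% (published cell
        # 64,827; the published factor differs from A(66,0.03) in the third
        # decimal, hence the relative tolerance)
        assert perinatal_lys(2267, _baseline()) == pytest.approx(64_827, rel=1e-4)

    def test_single_death_undiscounted(self):
        b = _baseline(discount_rate=0.0, perinatal_discount_horizon_years=66)
        assert perinatal_lys(1, b) == 66.0

    def test_optimistic_with_64_year_horizon(self):
        b = _baseline(perinatal_discount_horizon_years=64)
        assert perinatal_lys(5542, b) == pytest.approx(156_875, abs=156_875 * 0.001)


class TestMaternalLys:
    def test_single_age_group_closed_form(self):
        # A(36, 0.03) = 21.832 discounted years per death at midpoint 30
        assert maternal_lys(10, _baseline()) == pytest.approx(218.32, abs=0.05)

    def test_zero_rate_reduces_to_remaining_years(self):
        b = _baseline(discount_rate=0.0)
        assert maternal_lys(5, b) == 5 * 36.0

    def test_calibrated_distribution_reproduces_reference_cell(self):
        from anc_cea.synthetic import calibrated_maternal_age_shares

        b = _baseline(maternal_age_distribution=calibrated_maternal_age_shares())
        assert maternal_lys(26, b) == pytest.approx(539, rel=0.02)

    def test_midpoint_beyond_life_expectancy_rejected(self):
        with pytest.raises(ValueError):
            _baseline(maternal_age_distribution=((70.0, 1.0),))

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _baseline(maternal_age_distribution=((20.0, 0.5), (30.0, 0.4)))


class TestHealthGains:
    def test_optimistic_total_lys(self):
        from anc_cea.synthetic import calibrated_maternal_age_shares

        b = _baseline(maternal_age_distribution=calibrated_maternal_age_shares())
        gains = health_gains(b, OutcomeScenario("optimistic", 55.0, 52.5))
        assert gains.total_lys == pytest.approx(162_509, rel=0.001)
        assert gains.total_lys == gains.perinatal_lys + gains.maternal_lys

    def test_zero_reduction_gives_zero_gains(self):
        gains = health_gains(_baseline(), OutcomeScenario("null", 0.0, 0.0))
        assert gains.total_lys == 0.0
        assert gains.perinatal_deaths_averted == gains.maternal_deaths_averted == 0

    def test_deaths_averted_linear_in_reduction(self):
        b = _baseline()
        g1 = health_gains(b, OutcomeScenario("a", 20.0, 10.0))
        g2 = health_gains(b, OutcomeScenario("b", 40.0, 20.0))
        assert g2.perinatal_deaths_averted == pytest.approx(
            2 * g1.perinatal_deaths_averted, abs=1
        )
        assert g2.maternal_deaths_averted == pytest.approx(
            2 * g1.maternal_deaths_averted, abs=1
        )


def test_years_per_death_is_share_weighted_annuity():
    b = _baseline(maternal_age_distribution=((20.0, 0.5), (40.0, 0.5)))
    expected = 0.5 * annuity_factor(46, 0.03) + 0.5 * annuity_factor(26, 0.03)
    assert maternal_years_per_death(b) == pytest.approx(expected, abs=1e-12)
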