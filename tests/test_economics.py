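import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tobacco_burden.economics import (
    CATEGORIES,
    adjust_inflation,
    compute_costs,
    convert_currency,
    cost_shares,
    cost_table,
    direct_medical_cost,
    informal_care_cost,
    mincer_wage,
    presenteeism_cost,
    pv_future_income,
)
from tobacco_burden.parameters import GROUP_ORDER, EconomicParams


class TestUnitConversions:
    def test_published_inflation_factor(self):
        assert adjust_inflation(100.0, 0.1047) == pytest.approx(110.47)
        assert adjust_inflation(0.0, 0.1047) == 0.0
        assert adjust_inflation(50.0, 0.0) == 50.0

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            adjust_inflation(-1.0, 0.1)

    def test_published_exchange_rate(self):
        assert convert_currency(3.3, 3.3) == 1.0
        assert convert_currency(330.0, 3.3) == pytest.approx(100.0)
        assert convert_currency(0.0, 3.3) == 0.0

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            convert_currency(10.0, 0.0)

    def test_inflation_and_conversion_commute(self):
        a = convert_currency(adjust_inflation(123.4, 0.1047), 3.3)
        b = adjust_inflation(convert_currency(123.4, 3.3), 0.1047)
        assert a == pytest.approx(b)


class TestMincerWage:
    def test_zero_coefficients_give_unit_wage(self):
        econ = EconomicParams(
            mincer={"male": {"beta0": 0, "beta_edu": 0, "beta_age": 0, "beta_age2": 0}}
        )
        assert mincer_wage(40, "male", 11, econ) == 1.0

    def test_intercept_only(self):
        econ = EconomicParams(
            mincer={"male": {"beta0": np.log(100), "beta_edu": 0, "beta_age": 0, "beta_age2": 0}}
        )
        assert mincer_wage(40, "male", 11, econ) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        econ = EconomicParams(
            mincer={"male": {"beta0": 9, "beta_edu": 0.08, "beta_age": 0.05, "beta_age2": -0.0005}}
        )
        expected = np.exp(9 + 0.08 * 11 + 0.05 * 40 - 0.0005 * 1600)
        assert mincer_wage(40, "male", 11, econ) == pytest.approx(expected)


class TestPresentValue:
    def test_geometric_series_oracle(self):
        # w=100, g=0, r=5%, 2 years: 100/1.05 + 100/1.05^2
        econ = EconomicParams(discount_rate=0.05, wage_growth_rate=0.0,
                              retirement_age={"male": 65, "female": 60})
        pv = pv_future_income(63, "male", econ, wage_fn=lambda a, s: 100.0)
        assert pv == pytest.approx(100 / 1.05 + 100 / 1.05**2)
        assert pv == pytest.approx(185.94, abs=0.01)

    def test_growth_cancels_discount(self):
        econ = EconomicParams(discount_rate=0.05, wage_growth_rate=0.05,
                              retirement_age={"male": 65, "female": 60})
        pv = pv_future_income(55, "male", econ, wage_fn=lambda a, s: 70.0)
        assert pv == pytest.approx(70.0 * 10)

    def test_zero_at_and_beyond_retirement(self):
        econ = EconomicParams()
        assert pv_future_income(65, "male", econ) == 0.0
        assert pv_future_income(70, "male", econ) == 0.0

    def test_monotone_in_discount_growth_and_horizon(self):
        wage = lambda a, s: 100.0  # noqa: E731
        base = EconomicParams(discount_rate=0.05, wage_growth_rate=0.02)
        hi_r = EconomicParams(discount_rate=0.08, wage_growth_rate=0.02)
        hi_g = EconomicParams(discount_rate=0.05, wage_growth_rate=0.04)
        pv = lambda e, age=45: pv_future_income(age, "male", e, wage_fn=wage)  # noqa: E731
        assert pv(hi_r) < pv(base) < pv(hi_g)
        assert pv(base, age=50) < pv(base, age=45) < pv(base, age=40)


class TestSimpleCosts:
    def test_presenteeism_proportionality(self):
        assert presenteeism_cost(0.0, 1.0, 1000.0) == 0.0
        assert presenteeism_cost(0.2, 1.0, 1000.0) == pytest.approx(200.0)
        assert presenteeism_cost(0.4, 1.0, 1000.0) == pytest.approx(400.0)

    def test_informal_care_product(self):
        assert informal_care_cost(0.0, 5.0) == 0.0
        assert informal_care_cost(100.0, 5.0) == 500.0

    def test_direct_medical_applies_inflation_then_conversion(self):
        econ = EconomicParams(inflation_factor=0.1047, exchange_rate_pen_per_usd=3.3)
        # 10 case-years at 1000/yr -> 10,000 PEN-2015 -> inflated, converted
        assert direct_medical_cost(10.0, 1000.0, econ) == pytest.approx(
            10_000 * 1.1047 / 3.3
        )


class TestCostShares:
    def test_published_category_shares(self):
        shares = cost_shares([1285.2, 325.1, 453.0, 740.5])
        assert shares["direct_medical"] == 45.8
        assert shares["premature_mortality"] == 11.6
        assert shares["disability"] == 16.2
        assert shares["informal_care"] == 26.4

    def test_published_gdp_shares(self):
        # GDP implied by the published total-burden share of 1.28%
        gdp = 2803.7 / 0.0128
        shares = cost_shares([1285.2, 325.1, 453.0, 740.5], gdp_musd=gdp)
        assert shares["gdp_share"] == 1.28
        assert shares["gdp_share_direct"] == 0.59
        assert cost_shares([1.0, 1.0, 1.0, 1.0]).get("gdp_share") is None

    def test_single_category_is_100(self):
        assert cost_shares([10.0, 0, 0, 0])["direct_medical"] == 100.0

    def test_zero_total_not_applicable(self):
        assert cost_shares([0, 0, 0, 0])["direct_medical"] is None

    @given(vals=st.lists(st.floats(0.1, 1e6), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_shares_sum_to_100(self, vals):
        shares = cost_shares(vals)
        assert sum(shares[c] for c in CATEGORIES) == pytest.approx(100.0, abs=0.2)


class TestCostConservation:
    def test_grand_total_equals_both_decompositions(self, peru_model, paired_lifetime):
        factual, never = paired_lifetime
        costs = compute_costs(factual, never, peru_model)
        by_cat = sum(costs.category_total(c) for c in CATEGORIES)
        by_grp = sum(costs.group_total(g) for g in GROUP_ORDER)
        assert costs.grand_total == pytest.approx(by_cat)
        assert costs.grand_total == pytest.approx(by_grp)
        assert (costs.cells.to_numpy() >= 0).all()

    def test_cost_table_shape_and_total(self, peru_model, paired_lifetime):
        factual, never = paired_lifetime
        costs = compute_costs(factual, never, peru_model)
        table = cost_table(costs)
        total_row = table[(table["category"] == "total")].iloc[0]
        assert total_row["total"] == pytest.approx(costs.grand_total, abs=0.1)
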