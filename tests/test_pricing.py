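import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refbudgets import (
    FoodBasket,
    HouseholdType,
    PricingError,
    PricingPolicy,
    Sex,
    Unit,
    cheapest_price,
    per_type_cheapest,
    price_basket,
    weighted_category_price,
)
from refbudgets.core_model import BasketItem

from .conftest import make_obs

W5, W2 = 5.0 / 7.0, 2.0 / 7.0


def oracle_weighted_price(prices, trim=0.10):
    """Independent brute-force reference: explicit sort, trim and mean."""
    ps = sorted(prices)
    n = len(ps)
    k = min(int(math.floor(trim * n)), n - 1)
    kept = ps[: n - k]
    if len(kept) == 1:
        return kept[0]
    rest = kept[1:]
    return W5 * kept[0] + W2 * (sum(rest) / len(rest))


sorted_prices = st.lists(
    st.floats(0.1, 50.0, allow_nan=False, allow_infinity=False), min_size=1, max_size=12
).map(sorted)


class TestPerTypeCheapest:
    def test_min_per_type_sorted_by_price(self):
        obs = [
            make_obs(product_type="apple", price_eur=1.80),
            make_obs(product_type="apple", price_eur=1.50, shop="shop02"),
            make_obs(product_type="pear", price_eur=2.00),
        ]
        assert per_type_cheapest(obs, "fresh fruit") == [
            ("apple", 1.50),
            ("pear", 2.00),
        ]

    def test_single_observation_is_itself(self):
        obs = [make_obs(product_type="apple", price_eur=2.10)]
        assert per_type_cheapest(obs, "fresh fruit") == [("apple", 2.10)]

    def test_all_unacceptable_raises(self):
        obs = [make_obs(acceptable=False), make_obs(shop="shop02", acceptable=False)]
        with pytest.raises(PricingError, match="fresh fruit"):
            per_type_cheapest(obs, "fresh fruit")

    def test_price_ties_break_on_type_key(self):
        obs = [
            make_obs(product_type="pear", price_eur=1.0),
            make_obs(product_type="apple", price_eur=1.0),
        ]
        assert [t for t, _ in per_type_cheapest(obs, "fresh fruit")] == ["apple", "pear"]


class TestWeightedCategoryPrice:
    def test_single_type_collapses_weights(self):
        assert weighted_category_price([2.30]) == 2.30

    def test_worked_ten_type_example(self):
        # k = 1 discards the 5.00 outlier; mean of 1.20..2.60 is 1.90
        prices = [1.00, 1.20, 1.40, 1.60, 1.80, 2.00, 2.20, 2.40, 2.60, 5.00]
        expected = W5 * 1.00 + W2 * 1.90
        assert weighted_category_price(prices) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.2571428571, rel=1e-9)

    def test_two_types_nothing_trimmed(self):
        assert weighted_category_price([1.00, 3.00]) == pytest.approx(
            W5 * 1.0 + W2 * 3.0, rel=1e-12
        )

    def test_accepts_type_price_pairs(self):
        assert weighted_category_price([("apple", 1.0), ("pear", 3.0)]) == pytest.approx(
            W5 * 1.0 + W2 * 3.0
        )

    def test_empty_list_raises(self):
        with pytest.raises(PricingError):
            weighted_category_price([])

    def test_unsorted_input_rejected(self):
        with pytest.raises(PricingError, match="sorted"):
            weighted_category_price([2.0, 1.0])

    @pytest.mark.parametrize("n", range(1, 10))
    def test_trim_degenerates_below_ten_types(self, n):
        assert PricingPolicy().trim_count(n) == 0

    def test_ceil_trim_rule_discards_more(self):
        prices = [1.0, 2.0, 3.0, 4.0, 9.0]
        ceil_policy = PricingPolicy(trim_rule="ceil")
        assert PricingPolicy().trim_count(5) == 0
        assert ceil_policy.trim_count(5) == 1
        assert weighted_category_price(prices, ceil_policy) == pytest.approx(
            W5 * 1.0 + W2 * (2.0 + 3.0 + 4.0) / 3.0
        )

    def test_include_min_in_mean_option(self):
        got = weighted_category_price(
            [1.0, 3.0], PricingPolicy(exclude_min_from_mean=False)
        )
        assert got == pytest.approx(W5 * 1.0 + W2 * 2.0)

    def test_cheapest_set_option_averages_bottom_share(self):
        policy = PricingPolicy(cheapest_set_fraction=0.5)
        got = weighted_category_price([1.0, 2.0, 3.0, 4.0], policy)
        assert got == pytest.approx(W5 * 1.5 + W2 * 3.5)

    @given(prices=sorted_prices)
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, prices):
        assert weighted_category_price(prices) == pytest.approx(
            oracle_weighted_price(prices), rel=1e-12
        )

    @given(prices=sorted_prices)
    @settings(max_examples=300, deadline=None)
    def test_bracketed_by_retained_prices(self, prices):
        policy = PricingPolicy()
        kept = prices[: len(prices) - policy.trim_count(len(prices))]
        got = weighted_category_price(prices, policy)
        assert kept[0] - 1e-12 <= got <= kept[-1] + 1e-12


class TestCheapestPrice:
    def test_global_minimum(self):
        obs = [
            make_obs(product_type="white", price_eur=0.90, category="bread"),
            make_obs(product_type="rye", price_eur=1.10, category="bread"),
            make_obs(product_type="white", price_eur=0.85, category="bread", shop="s2"),
        ]
        assert cheapest_price(obs, "bread") == 0.85

    def test_tie_is_value_identical(self):
        obs = [
            make_obs(price_eur=1.00, category="bread"),
            make_obs(price_eur=1.00, category="bread", shop="s2"),
        ]
        assert cheapest_price(obs, "bread") == 1.00

    @given(prices=sorted_prices)
    @settings(max_examples=200, deadline=None)
    def test_never_above_weighted_price(self, prices):
        obs = [
            make_obs(product_type=f"t{i:03d}", price_eur=p)
            for i, p in enumerate(prices)
        ]
        assert cheapest_price(obs, "fresh fruit") <= weighted_category_price(
            per_type_cheapest(obs, "fresh fruit")
        ) + 1e-12


def _basket(items):
    h = HouseholdType("single_woman", ((Sex.F, 40.0),))
    return FoodBasket("BE", h, tuple(items))


class TestPriceBasket:
    def test_empty_basket_costs_nothing(self):
        priced = price_basket(_basket([]), [])
        assert priced.total == 0.0

    def test_worked_multiplication(self):
        # 10 kg/month of fresh fruit at the worked weighted price
        prices = [1.00, 1.20, 1.40, 1.60, 1.80, 2.00, 2.20, 2.40, 2.60, 5.00]
        obs = [
            make_obs(product_type=f"t{i:02d}", price_eur=p)
            for i, p in enumerate(prices)
        ]
        basket = _basket([BasketItem("fresh fruit", 10_000.0, Unit.G, "weighted")])
        priced = price_basket(basket, obs)
        assert priced.total == pytest.approx(10.0 * (W5 + W2 * 1.9), rel=1e-12)

    def test_doubling_quantities_doubles_total(self):
        obs = [
            make_obs(product_type="apple", price_eur=1.5),
            make_obs(category="bread", product_type="white", price_eur=2.0),
        ]
        items = [
            BasketItem("fresh fruit", 5000.0, Unit.G, "weighted"),
            BasketItem("bread", 8000.0, Unit.G, "cheapest"),
        ]
        doubled = [
            BasketItem(it.category, 2 * it.monthly_gross_quantity, it.unit, it.pricing_mode)
            for it in items
        ]
        t1 = price_basket(_basket(items), obs).total
        t2 = price_basket(_basket(doubled), obs).total
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_missing_categories_reported_together(self):
        basket = _basket(
            [
                BasketItem("fresh fruit", 100.0, Unit.G, "weighted"),
                BasketItem("bread", 100.0, Unit.G, "cheapest"),
            ]
        )
        with pytest.raises(PricingError) as exc:
            price_basket(basket, [])
        assert "fresh fruit" in str(exc.value) and "bread" in str(exc.value)

    def test_millilitre_items_convert_to_litres(self):
        obs = [make_obs(category="milk", product_type="semi", unit="L", price_eur=0.9)]
        basket = _basket([BasketItem("milk", 12_000.0, Unit.ML, "cheapest")])
        priced = price_basket(basket, obs)
        assert priced.total == pytest.approx(12.0 * 0.9, rel=1e-12)

    def test_raising_one_observation_never_lowers_total(self):
        import numpy as np

        rng = np.random.default_rng(42)
        for _ in range(50):
            n_types = rng.integers(1, 7)
            obs = [
                make_obs(
                    product_type=f"t{t}",
                    shop=f"s{s}",
                    price_eur=float(rng.uniform(0.5, 5.0)),
                )
                for t in range(n_types)
                for s in range(2)
            ]
            basket = _basket([BasketItem("fresh fruit", 3000.0, Unit.G, "weighted")])
            before = price_basket(basket, obs).total
            i = int(rng.integers(0, len(obs)))
            bumped = obs[:]
            o = obs[i]
            bumped[i] = make_obs(
                product_type=o.product_type,
                shop=o.shop,
                price_eur=o.price_eur + float(rng.uniform(0.01, 2.0)),
            )
            assert price_basket(basket, bumped).total >= before - 1e-12
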