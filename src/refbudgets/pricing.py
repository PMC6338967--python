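"""Category unit prices and basket costing.

Two pricing rules coexist.  Large-variety categories (fresh fruit, fresh
vegetables, fish, meats, cheese, ...) get a trimmed weighted price that
keeps the basket cheap while still paying for variety: per product type,
take the cheapest acceptable observation; sort the per-type prices; discard
the top decile of types; weight the cheapest retained price 5/7 and the
mean of the remaining retained prices 2/7.  Every other category simply
takes the lowest acceptable price.

Costing multiplies monthly gross quantities (g or mL) by unit prices
(EUR per kg or L), converting with an exact factor of 1000.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from .core_model import (
    DEFAULT_PRICING_POLICY,
    FoodBasket,
    PricedBasket,
    PricingError,
    PricingPolicy,
    ProductObservation,
)

__all__ = [
    "per_type_cheapest",
    "weighted_category_price",
    "cheapest_price",
    "category_price",
    "price_basket",
]


def per_type_cheapest(
    observations: Iterable[ProductObservation], category: str
) -> list[tuple[str, float]]:
    """Cheapest acceptable unit price per product type within a category.

    Returns (product_type, EUR per kg-or-L) pairs sorted ascending by
    (price, type key); the lexicographic tie-break keeps runs deterministic.
    """
    best: dict[str, float] = {}
    for obs in observations:
        if obs.category != category or not obs.acceptable:
            continue
        p = obs.unit_price
        if obs.product_type not in best or p < best[obs.product_type]:
            best[obs.product_type] = p
    if not best:
        raise PricingError(f"no acceptable observations for category {category!r}")
    return sorted(best.items(), key=lambda tp: (tp[1], tp[0]))


def _prices(per_type: Sequence) -> list[float]:
    # accept either bare prices or (type, price) pairs
    vals = [p[1] if isinstance(p, tuple) else float(p) for p in per_type]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise PricingError("per-type price list must be sorted ascending")
    return vals


def weighted_category_price(
    per_type_prices: Sequence, policy: PricingPolicy = DEFAULT_PRICING_POLICY
) -> float:
    """Trimmed weighted category price from sorted per-type cheapest prices.

    Discard the ``policy.trim_count(n)`` most expensive types (floor of
    trim_fraction x n by default, so nothing is discarded below 10 types at
    the 10% trim).  If a single type remains its price is returned — the
    weights collapse.  Otherwise the price is

        weight_cheapest x p_min + weight_rest x mean(rest)

    where ``rest`` excludes p_min by default.  The result always lies within
    [min, max] of the retained prices because the weights sum to one.
    """
    prices = _prices(per_type_prices)
    if not prices:
        raise PricingError("empty per-type price list")
    n = len(prices)
    retained = prices[: n - policy.trim_count(n)]
    if len(retained) == 1:
        return retained[0]

    if policy.cheapest_set_fraction is not None:
        m = max(1, math.floor(policy.cheapest_set_fraction * len(retained)))
    else:
        m = 1
    cheap = math.fsum(retained[:m]) / m
    rest = retained[m:] if policy.exclude_min_from_mean else retained
    if not rest:
        return cheap
    rest_mean = math.fsum(rest) / len(rest)
    return policy.weight_cheapest * cheap + policy.weight_rest * rest_mean


def cheapest_price(
    observations: Iterable[ProductObservation], category: str
) -> float:
    """Lowest acceptable unit price in the category (EUR per kg or L)."""
    prices = [
        obs.unit_price
        for obs in observations
        if obs.category == category and obs.acceptable
    ]
    if not prices:
        raise PricingError(f"no acceptable observations for category {category!r}")
    return min(prices)


def category_price(
    observations: Iterable[ProductObservation],
    category: str,
    policy: PricingPolicy = DEFAULT_PRICING_POLICY,
    mode: str | None = None,
) -> float:
    """Unit price for one category under the policy-selected rule.

    ``mode`` overrides the policy's category list; otherwise categories in
    ``policy.weighted_categories`` are weighted and the rest take the
    cheapest price.
    """
    observations = list(observations)
    if mode is None:
        mode = "weighted" if category in policy.weighted_categories else "cheapest"
    if mode == "weighted":
        return weighted_category_price(per_type_cheapest(observations, category), policy)
    return cheapest_price(observations, category)


def price_basket(
    basket: FoodBasket,
    survey: Iterable[ProductObservation],
    policy: PricingPolicy = DEFAULT_PRICING_POLICY,
) -> PricedBasket:
    """Cost a basket against one country's price survey.

    item_cost = quantity (g or mL) / 1000 x unit price (EUR per kg or L).
    Unpriceable categories are collected and reported together so one run
    surfaces every gap in the survey at once.
    """
    survey = list(survey)
    prices: dict[str, float] = {}
    missing: list[str] = []
    for item in basket.items:
        try:
            prices[item.category] = category_price(
                survey, item.category, policy, mode=item.pricing_mode
            )
        except PricingError:
            missing.append(item.category)
    if missing:
        raise PricingError(f"unpriceable categories: {sorted(missing)}")

    costs = {
        item.category: item.monthly_gross_quantity / 1000.0 * prices[item.category]
        for item in basket.items
    }
    return PricedBasket(
        basket=basket,
        item_prices=prices,
        item_costs=costs,
        total=math.fsum(costs.values()),
    )
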