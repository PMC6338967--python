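"""Synthetic FBDG tables, retail price surveys and income references.

No country's actual 2015 price survey or guideline table is distributed, so
the pipeline ships generators that emulate the structure of all three
inputs.  Daily food-group amounts are drawn uniformly inside the spans
observed across the 26 national guidelines (fruit and vegetables 300-400 g,
dairy 215-710 g, meat/fish/eggs 90-339 g, residual 25-155 g); per-type
retail prices are lognormal, giving the right skew of real shelves — many
cheap staples, a few expensive variants — so the 10% trim of the weighted
price procedure is actually exercised.

Determinism: every generator derives an independent substream per
(category) or (country, ...) key from the user seed, so adding a country or
category never perturbs the draws of another.  Price *structure* (the
lognormal draws per category, type and shop) is shared across countries;
country price levels differ only through an explicit multiplier.  That
makes cross-country cost differences exactly proportional to the
multipliers, which is what a controlled comparison of the pricing stage
needs.
"""

from __future__ import annotations

import math
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_model import (
    DomainError,
    FbdgEntry,
    FoodGroup,
    IncomeReference,
    ProductObservation,
    Sex,
    Unit,
)

__all__ = [
    "DEFAULT_GROUP_RANGES",
    "GROUP_CATEGORIES",
    "DEFAULT_DEMOGRAPHICS",
    "CATEGORY_BASE_PRICES",
    "gen_fbdg",
    "gen_price_survey",
    "gen_incomes",
    "default_price_scale",
]

#: Uniform ranges for daily food-group amounts, (lo, hi, unit) per group.
#: Fruit, vegetables, dairy, meat/fish/eggs and residual follow the spans
#: observed across the 26 national guidelines; grains, fats and liquids are
#: set to ranges a nutritionist would call typical for adult recommendations.
DEFAULT_GROUP_RANGES: dict[FoodGroup, tuple[float, float, Unit]] = {
    FoodGroup.FRUIT: (300.0, 400.0, Unit.G),
    FoodGroup.VEGETABLES: (300.0, 400.0, Unit.G),
    FoodGroup.GRAINS: (200.0, 350.0, Unit.G),
    FoodGroup.DAIRY: (215.0, 710.0, Unit.G),
    FoodGroup.MEAT_FISH_EGGS: (90.0, 339.0, Unit.G),
    FoodGroup.FATS: (20.0, 60.0, Unit.G),
    FoodGroup.LIQUIDS: (1500.0, 2500.0, Unit.ML),
    FoodGroup.RESIDUAL: (25.0, 155.0, Unit.G),
}

#: How each group's daily amount is split into purchasable categories.
#: The split mixes weighted-procedure categories (fresh fruit, fresh
#: vegetables, cheese, lean meat, fresh fish) with lowest-price ones
#: (bread, potatoes, milk, eggs, ...) so both pricing rules run end to end.
GROUP_CATEGORIES: dict[FoodGroup, tuple[tuple[str, float], ...]] = {
    FoodGroup.FRUIT: (("fresh fruit", 1.0),),
    FoodGroup.VEGETABLES: (("fresh vegetables", 1.0),),
    FoodGroup.GRAINS: (("bread", 0.6), ("potatoes", 0.4)),
    FoodGroup.DAIRY: (("milk", 0.8), ("cheese", 0.2)),
    FoodGroup.MEAT_FISH_EGGS: (
        ("lean meat", 0.40),
        ("fresh fish", 0.35),
        ("eggs", 0.25),
    ),
    FoodGroup.FATS: (("cooking oil", 1.0),),
    FoodGroup.LIQUIDS: (("water", 1.0),),
    FoodGroup.RESIDUAL: (("residual foods", 1.0),),
}

#: Demographic bands generated per country: the two adult bands the
#: reference households need, plus a unisex child band.
DEFAULT_DEMOGRAPHICS: tuple[tuple[Sex, float, float], ...] = (
    (Sex.F, 18.0, 64.0),
    (Sex.M, 18.0, 64.0),
    (Sex.ANY, 6.0, 17.0),
)

#: Median shelf price per category, EUR per kg (or per L for liquids);
#: the lognormal location parameter is the log of these.
CATEGORY_BASE_PRICES: dict[str, float] = {
    "fresh fruit": 1.8,
    "fresh vegetables": 1.6,
    "bread": 2.0,
    "potatoes": 0.9,
    "milk": 0.9,
    "cheese": 7.0,
    "lean meat": 7.5,
    "fresh fish": 9.0,
    "eggs": 3.5,
    "cooking oil": 2.5,
    "water": 0.4,
    "residual foods": 3.0,
}

_LIQUID_CATEGORIES = frozenset({"milk", "water"})


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Independent substream for (seed, *keys): stable across runs and
    unaffected by which other keys are generated in the same call."""
    return np.random.default_rng([int(seed)] + [zlib.crc32(k.encode()) for k in keys])


def gen_fbdg(
    countries: Sequence[str],
    seed: int,
    group_ranges: Mapping[FoodGroup, tuple[float, float, Unit]] | None = None,
    group_categories: Mapping[FoodGroup, tuple[tuple[str, float], ...]] | None = None,
    demographics: Sequence[tuple[Sex, float, float]] = DEFAULT_DEMOGRAPHICS,
) -> list[FbdgEntry]:
    """Generate a synthetic FBDG table for the given countries.

    Per (country, food group, demographic band) a daily amount is drawn
    uniformly within the group's range and split across the group's
    categories with fixed shares.  Deterministic given the seed; each
    (country, group) pair has its own substream.
    """
    if not countries:
        raise DomainError("need at least one country")
    ranges = dict(group_ranges or DEFAULT_GROUP_RANGES)
    cats = dict(group_categories or GROUP_CATEGORIES)

    entries: list[FbdgEntry] = []
    for country in countries:
        for group in FoodGroup:
            if group not in ranges:
                continue
            lo, hi, unit = ranges[group]
            rng = _rng(seed, country, group.value)
            for sex, age_lo, age_hi in demographics:
                amount = float(rng.uniform(lo, hi))
                for category, share in cats.get(group, ((group.value, 1.0),)):
                    entries.append(
                        FbdgEntry(
                            country=country,
                            group=group,
                            category=category,
                            sex=Sex(sex),
                            age_lo=age_lo,
                            age_hi=age_hi,
                            daily_net_amount=amount * share,
                            unit=unit,
                        )
                    )
    return entries


def gen_price_survey(
    countries: Sequence[str],
    n_shops: int = 4,
    types_per_category: int = 10,
    price_scale: Mapping[str, float] | None = None,
    seed: int = 0,
    sigma: float = 0.35,
    base_prices: Mapping[str, float] | None = None,
    unacceptable_rate: float = 0.05,
) -> dict[str, list[ProductObservation]]:
    """Generate one synthetic retail price survey per country.

    Per category, product type and shop, the price is

        country multiplier x Lognormal(log(base price), sigma)

    with roughly ``unacceptable_rate`` of observations flagged as not of
    sufficient quality.  The lognormal draws and the quality flags are keyed
    by (seed, category) only, so two countries differ exactly by the ratio
    of their multipliers — scale equivariance by construction.
    """
    if n_shops < 1 or types_per_category < 1:
        raise DomainError("n_shops and types_per_category must be >= 1")
    scale = dict(price_scale or {})
    for c in countries:
        scale.setdefault(c, 1.0)
        if scale[c] <= 0:
            raise DomainError(f"price multiplier for {c!r} must be > 0")
    bases = dict(base_prices or CATEGORY_BASE_PRICES)

    # country-independent price structure: one draw per (category, type, shop)
    structure: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for category, base in bases.items():
        rng = _rng(seed, "prices", category)
        mu = np.log(base)
        structure[category] = np.exp(
            rng.normal(mu, sigma, size=(types_per_category, n_shops))
        ) if sigma > 0 else np.full((types_per_category, n_shops), base)
        flags[category] = rng.random(size=(types_per_category, n_shops)) >= unacceptable_rate

    surveys: dict[str, list[ProductObservation]] = {}
    for country in countries:
        mult = scale[country]
        obs: list[ProductObservation] = []
        for category in sorted(bases):
            unit = "L" if category in _LIQUID_CATEGORIES else "kg"
            prices = structure[category]
            ok = flags[category]
            for t in range(types_per_category):
                for s in range(n_shops):
                    obs.append(
                        ProductObservation(
                            shop=f"shop{s + 1:02d}",
                            category=category,
                            product_type=f"{category} type {t + 1:02d}",
                            variant="standard",
                            unit_size=1.0,
                            unit=unit,
                            price_eur=float(mult * prices[t, s]),
                            acceptable=bool(ok[t, s]),
                        )
                    )
        surveys[country] = obs
    return surveys


def gen_incomes(
    countries: Sequence[str],
    income_range: tuple[float, float] = (2400.0, 40000.0),
    seed: int = 0,
) -> list[IncomeReference]:
    """Log-uniform median equivalised disposable incomes, EUR per year.

    The default range spans the EU-like spread between the poorest and the
    richest member states' medians (roughly a factor of 16).  Incomes are
    ratio-scale and the actual national medians cluster towards the low end
    of that span, so draws are uniform on the log scale; that spread is what
    drives income shares apart far more than basket costs do.
    """
    lo, hi = income_range
    if not (0 < lo <= hi):
        raise DomainError(f"income range must satisfy 0 < lo <= hi, got {income_range}")
    out = []
    for country in countries:
        rng = _rng(seed, "income", country)
        draw = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        out.append(
            IncomeReference(
                country=country,
                # exp/log round-trip can step just outside the range
                median_income_eur_year=min(max(draw, lo), hi),
            )
        )
    return out


def default_price_scale(
    incomes: Iterable[IncomeReference],
    mult_range: tuple[float, float] = (0.75, 1.5),
) -> dict[str, float]:
    """Country price multipliers mildly increasing with income.

    Richer countries have higher price levels, but far less than
    proportionally — price levels span about a factor of two while incomes
    span more than a factor of ten.  Mapping multipliers linearly onto the
    income range reproduces that compression.
    """
    incomes = list(incomes)
    lo_m, hi_m = mult_range
    if not (0 < lo_m <= hi_m):
        raise DomainError("mult_range must satisfy 0 < lo <= hi")
    values = [r.median_income_eur_year for r in incomes]
    lo_i, hi_i = min(values), max(values)
    span = hi_i - lo_i
    return {
        r.country: (
            lo_m
            if span == 0
            else lo_m + (hi_m - lo_m) * (r.median_income_eur_year - lo_i) / span
        )
        for r in incomes
    }
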