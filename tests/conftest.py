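import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from refbudgets import (
    DEFAULT_WASTE_POLICY,
    FbdgEntry,
    FoodGroup,
    ProductObservation,
    Sex,
    Unit,
)


def make_entry(
    country="BE",
    group=FoodGroup.FRUIT,
    category="fresh fruit",
    sex=Sex.ANY,
    age_lo=0.0,
    age_hi=99.0,
    amount=300.0,
    unit=Unit.G,
):
    return FbdgEntry(
        country=country,
        group=group,
        category=category,
        sex=sex,
        age_lo=age_lo,
        age_hi=age_hi,
        daily_net_amount=amount,
        unit=unit,
    )


def make_obs(
    shop="shop01",
    category="fresh fruit",
    product_type="apple",
    variant="standard",
    unit_size=1.0,
    unit="kg",
    price_eur=1.5,
    acceptable=True,
):
    return ProductObservation(
        shop=shop,
        category=category,
        product_type=product_type,
        variant=variant,
        unit_size=unit_size,
        unit=unit,
        price_eur=price_eur,
        acceptable=acceptable,
    )


@pytest.fixture
def tiny_fbdg():
    """A minimal unisex single-country table: one category per food group."""
    rows = [
        (FoodGroup.FRUIT, "fresh fruit", 300.0, Unit.G),
        (FoodGroup.VEGETABLES, "fresh vegetables", 350.0, Unit.G),
        (FoodGroup.GRAINS, "potatoes", 200.0, Unit.G),
        (FoodGroup.DAIRY, "milk", 400.0, Unit.G),
        (FoodGroup.MEAT_FISH_EGGS, "eggs", 50.0, Unit.G),
        (FoodGroup.FATS, "cooking oil", 30.0, Unit.G),
        (FoodGroup.LIQUIDS, "water", 1500.0, Unit.ML),
        (FoodGroup.RESIDUAL, "residual foods", 80.0, Unit.G),
    ]
    return [
        make_entry(group=g, category=c, amount=a, unit=u) for g, c, a, u in rows
    ]


@pytest.fixture
def waste_policy():
    return DEFAULT_WASTE_POLICY
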