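"""Translate daily FBDG net recommendations into monthly gross baskets.

Three steps per household: resolve each member's daily net amounts from the
recommendation table (with an explicit demographic fallback ladder), convert
net to gross with the waste policy, and scale to a month.  Quantities are
additive over members by construction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .core_model import (
    DEFAULT_PRICING_POLICY,
    BasketItem,
    DomainError,
    FbdgEntry,
    FoodBasket,
    HouseholdType,
    PricingPolicy,
    ResolutionError,
    Sex,
    Unit,
    WasteConvention,
    WastePolicy,
)

__all__ = [
    "DAYS_PER_MONTH",
    "ADULT_REFERENCE_AGE",
    "gross_amount",
    "member_daily_amounts",
    "build_basket",
]

#: 365.25 / 12 — a month of average calendar length.
DAYS_PER_MONTH = 30.4375

#: Age used for the adult-female fallback when no entry covers a member.
ADULT_REFERENCE_AGE = 40.0


def gross_amount(
    net: float,
    waste_fraction: float,
    convention: WasteConvention = WasteConvention.ADD_ON_NET,
) -> float:
    """Gross (purchased) amount needed to yield ``net`` after waste.

    ``add_on_net`` returns net x (1 + w); ``divide_by_edible`` returns
    net / (1 - w).  Both reduce to the identity at w = 0 and never fall
    below the net amount.
    """
    if net < 0:
        raise DomainError(f"net amount must be >= 0, got {net}")
    if not (0.0 <= waste_fraction < 1.0):
        raise DomainError(f"waste fraction must be in [0, 1), got {waste_fraction}")
    convention = WasteConvention(convention)
    if convention is WasteConvention.ADD_ON_NET:
        return net * (1.0 + waste_fraction)
    return net / (1.0 - waste_fraction)


def _specificity_key(entry: FbdgEntry) -> tuple:
    # sex-specific beats 'any'; then the narrowest age band; then stable order
    return (entry.sex is Sex.ANY, entry.age_hi - entry.age_lo, entry.age_lo)


def _select(candidates: Sequence[FbdgEntry], sex: Sex, age: float) -> FbdgEntry | None:
    """Most specific entry covering (sex, age), following the fallback ladder:
    exact (sex, age) match -> sex=any with matching age -> None."""
    matching = [e for e in candidates if e.matches(sex, age)]
    if not matching:
        return None
    return min(matching, key=_specificity_key)


def member_daily_amounts(
    fbdg: Iterable[FbdgEntry],
    member: tuple[Sex | str, float],
    country: str | None = None,
) -> dict[str, tuple[float, Unit]]:
    """Resolve one member's daily net amount for every category.

    Fallback ladder per category: the most specific entry matching the
    member's (sex, age) — sex-specific beats unisex, narrower age band beats
    wider — then, if no entry covers the member's age, the adult-female
    amounts (age ``ADULT_REFERENCE_AGE``).  The ladder is deliberately
    explicit because most national guidelines are written for adults and say
    nothing about children's portions.

    Returns a map category -> (daily net amount, unit).
    """
    sex, age = Sex(member[0]), float(member[1])
    entries = [e for e in fbdg if country is None or e.country == country]
    if not entries:
        raise ResolutionError(
            f"no FBDG entries available for country {country!r}"
        )
    by_category: dict[str, list[FbdgEntry]] = {}
    for e in entries:
        by_category.setdefault(e.category, []).append(e)

    out: dict[str, tuple[float, Unit]] = {}
    for category, candidates in by_category.items():
        chosen = _select(candidates, sex, age)
        if chosen is None:  # adult-female fallback
            chosen = _select(candidates, Sex.F, ADULT_REFERENCE_AGE)
        if chosen is None:
            raise ResolutionError(
                f"no FBDG entry resolves for category {category!r} and member "
                f"(sex={sex.value}, age={age}), and the adult-female fallback "
                "is empty"
            )
        out[category] = (chosen.daily_net_amount, chosen.unit)
    return out


def build_basket(
    fbdg: Iterable[FbdgEntry],
    waste: WastePolicy,
    household: HouseholdType,
    days_per_month: float = DAYS_PER_MONTH,
    pricing_policy: PricingPolicy = DEFAULT_PRICING_POLICY,
    country: str | None = None,
) -> FoodBasket:
    """Monthly gross purchase quantities for one household.

    Per category: sum over members of gross_amount(daily net, waste) x
    days_per_month.  The pricing mode is ``weighted`` exactly for the
    categories in ``pricing_policy.weighted_categories``.
    """
    entries = list(fbdg)
    if country is None:
        countries = {e.country for e in entries}
        if len(countries) != 1:
            raise DomainError(
                f"country is ambiguous ({sorted(countries)}); pass country="
            )
        country = countries.pop()
    else:
        entries = [e for e in entries if e.country == country]

    totals: dict[str, float] = {}
    units: dict[str, Unit] = {}
    for member in household.members:
        amounts = member_daily_amounts(entries, member, country=country)
        for category, (net, unit) in amounts.items():
            if category in units and units[category] is not unit:
                raise DomainError(f"inconsistent units for category {category!r}")
            units[category] = unit
            gross = gross_amount(net, waste.fraction(category), waste.convention)
            totals[category] = totals.get(category, 0.0) + gross * days_per_month

    items = tuple(
        BasketItem(
            category=category,
            monthly_gross_quantity=totals[category],
            unit=units[category],
            pricing_mode=(
                "weighted"
                if category in pricing_policy.weighted_categories
                else "cheapest"
            ),
        )
        for category in sorted(totals)
    )
    return FoodBasket(country=country, household=household, items=items)
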