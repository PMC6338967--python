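"""Domain types and table I/O shared by every stage of the pipeline.

The pipeline turns national food-based dietary guidelines (FBDG) into
monthly food baskets for standardised household types, prices the baskets
against a small retail price survey, and expresses the cost as a share of
median equivalised disposable income.  This module holds the validated
record types those stages exchange and the CSV/JSON readers and writers
for the fixed interchange schemas:

* ``fbdg.csv``     — country, group, category, sex, age_lo, age_hi, amount, unit
* ``prices.csv``   — shop, category, product_type, variant, unit_size, unit,
  price_eur, acceptable
* ``incomes.csv``  — country, median_income_eur_year
* ``basket.csv``   — country, household_id, category, monthly_gross_quantity,
  unit, pricing_mode
* ``priced_baskets.csv`` — country, household_id, category, unit_price,
  monthly_cost, total

All CSV files are UTF-8, comma-separated, decimal point, header row
required.  Prices are normalised at load time to EUR per kg (solids) or
EUR per L (liquids) so that costing always happens on one denominator.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FoodGroup",
    "Unit",
    "Sex",
    "WasteConvention",
    "FbdgEntry",
    "WastePolicy",
    "PricingPolicy",
    "HouseholdType",
    "ProductObservation",
    "BasketItem",
    "FoodBasket",
    "PricedBasket",
    "IncomeReference",
    "LoadError",
    "DomainError",
    "PricingError",
    "ResolutionError",
    "PILOT_COUNTRIES",
    "WEIGHTED_CATEGORIES",
    "DEFAULT_WASTE_POLICY",
    "DEFAULT_PRICING_POLICY",
    "REFERENCE_HOUSEHOLDS",
    "load_fbdg",
    "write_fbdg",
    "load_price_survey",
    "write_price_survey",
    "load_incomes",
    "write_incomes",
    "load_basket",
    "write_baskets",
    "write_priced_baskets",
    "write_priced_baskets_json",
]


class LoadError(ValueError):
    """A table row failed validation; the message names the 1-based row."""


class DomainError(ValueError):
    """An argument violates a domain precondition (e.g. waste fraction >= 1)."""


class PricingError(ValueError):
    """A category cannot be priced from the available observations."""


class ResolutionError(LookupError):
    """No FBDG entry resolves for a household member, even after fallback."""


class FoodGroup(str, enum.Enum):
    """The eight aggregate food groups used in the cross-country comparison.

    ``grains`` covers bread, rice, pasta, pulses and potatoes; ``liquids``
    is water and other everyday beverages (milk sits in ``dairy``);
    ``residual`` collects salt, sugar, spices, sauces and sweets.
    """

    FRUIT = "fruit"
    VEGETABLES = "vegetables"
    GRAINS = "grains"
    DAIRY = "dairy"
    MEAT_FISH_EGGS = "meat_fish_eggs"
    FATS = "fats"
    LIQUIDS = "liquids"
    RESIDUAL = "residual"


class Unit(str, enum.Enum):
    G = "g"
    ML = "mL"

    @property
    def base(self) -> str:
        """The pricing denominator: kg for solids, L for liquids."""
        return "kg" if self is Unit.G else "L"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    ANY = "any"


class WasteConvention(str, enum.Enum):
    """How a net (consumed) amount is converted to a gross (purchased) one.

    ``add_on_net`` multiplies the net amount by (1 + w); ``divide_by_edible``
    divides by (1 - w), the standard edible-portion convention.
    """

    ADD_ON_NET = "add_on_net"
    DIVIDE_BY_EDIBLE = "divide_by_edible"


#: The 26 participating countries (EU Member States minus IE and UK).
PILOT_COUNTRIES = frozenset(
    {
        "AT", "BE", "BG", "CY", "CZ", "DE", "DK", "EE", "EL", "ES",
        "FI", "FR", "HR", "HU", "IT", "LT", "LU", "LV", "MT", "NL",
        "PL", "PT", "RO", "SE", "SK", "SI",
    }
)

#: The 15 fresh/large-variety categories priced with the trimmed weighted
#: procedure; everything else takes the lowest suitable price.
WEIGHTED_CATEGORIES = frozenset(
    {
        "fresh fruit",
        "canned fruit",
        "fruit puree",
        "frozen fruit",
        "dried fruit",
        "fresh vegetables",
        "frozen prepared & unprepared vegetables",
        "canned vegetables",
        "fresh fish",
        "frozen fish",
        "canned fish",
        "lean meat",
        "fat meat",
        "charcuterie",
        "cheese",
    }
)


def _check_country(country: str, row: int | None = None) -> str:
    where = f"row {row}: " if row is not None else ""
    if not (len(country) == 2 and country.isalpha() and country.isupper()):
        raise LoadError(f"{where}country code {country!r} is not ISO-3166 alpha-2")
    if country not in PILOT_COUNTRIES:
        warnings.warn(
            f"country code {country!r} is not one of the 26 pilot countries",
            stacklevel=3,
        )
    return country


@dataclass(frozen=True)
class FbdgEntry:
    """One daily net-amount recommendation for one category and demographic.

    Parameters
    ----------
    country : str
        ISO-3166 alpha-2 code.
    group : FoodGroup
        Aggregate food group the category belongs to.
    category : str
        Free-text category key, e.g. ``"fresh fruit"`` or ``"potatoes"``.
    sex : Sex
        Target sex, ``Sex.ANY`` for unisex recommendations.
    age_lo, age_hi : float
        Inclusive age band in years.
    daily_net_amount : float
        Grams (solids) or millilitres (liquids) per day, net of waste.
    unit : Unit
    """

    country: str
    group: FoodGroup
    category: str
    sex: Sex
    age_lo: float
    age_hi: float
    daily_net_amount: float
    unit: Unit

    def __post_init__(self) -> None:
        if self.daily_net_amount < 0:
            raise DomainError(
                f"daily_net_amount must be >= 0, got {self.daily_net_amount}"
            )
        if self.age_lo > self.age_hi:
            raise DomainError(f"age band [{self.age_lo}, {self.age_hi}] is inverted")

    def matches(self, sex: Sex, age: float) -> bool:
        """True if this entry's demographic covers (sex, age)."""
        return (self.sex is Sex.ANY or self.sex is sex) and (
            self.age_lo <= age <= self.age_hi
        )


@dataclass(frozen=True)
class WastePolicy:
    """Category-level waste fractions plus the gross-conversion convention.

    Categories absent from the map imply zero waste.  The default policy
    carries the six standard percentages used across all countries:
    fresh fruit 22%, fresh vegetables 28%, potatoes 10%, fish 30%,
    fatter meat 20% and eggs 12%.
    """

    waste_fraction: Mapping[str, float] = field(default_factory=dict)
    convention: WasteConvention = WasteConvention.ADD_ON_NET

    def __post_init__(self) -> None:
        for cat, w in self.waste_fraction.items():
            if not (0.0 <= w < 1.0):
                raise DomainError(
                    f"waste fraction for {cat!r} must be in [0, 1), got {w}"
                )

    def fraction(self, category: str) -> float:
        return self.waste_fraction.get(category, 0.0)


DEFAULT_WASTE_POLICY = WastePolicy(
    waste_fraction={
        "fresh fruit": 0.22,
        "fresh vegetables": 0.28,
        "potatoes": 0.10,
        "fresh fish": 0.30,
        "frozen fish": 0.30,
        "fat meat": 0.20,
        "eggs": 0.12,
    },
    convention=WasteConvention.ADD_ON_NET,
)


@dataclass(frozen=True)
class PricingPolicy:
    """Parameters of the category-price rules.

    For the ``weighted_categories``, the per-type cheapest prices are sorted,
    the top ``trim_fraction`` most expensive types are discarded, and the
    category price is ``weight_cheapest`` x the cheapest retained price plus
    ``weight_rest`` x the mean of the remaining retained prices.  Every other
    category takes the lowest acceptable price outright.

    Options with a genuinely open reading are explicit:

    * ``trim_rule`` — ``"floor"`` (default, discards less) or ``"ceil"``.
    * ``exclude_min_from_mean`` — whether the cheapest retained price is left
      out of the "more expensive items" mean (default True: it already
      carries the 5/7 weight).
    * ``cheapest_set_fraction`` — if set, "the cheapest products" means the
      mean of the bottom fraction of retained types rather than the single
      cheapest one.
    """

    weight_cheapest: float = 5.0 / 7.0
    weight_rest: float = 2.0 / 7.0
    trim_fraction: float = 0.10
    weighted_categories: frozenset[str] = WEIGHTED_CATEGORIES
    trim_rule: str = "floor"
    exclude_min_from_mean: bool = True
    cheapest_set_fraction: float | None = None

    def __post_init__(self) -> None:
        if abs(self.weight_cheapest + self.weight_rest - 1.0) > 1e-12:
            raise DomainError(
                "weight_cheapest + weight_rest must equal 1, got "
                f"{self.weight_cheapest} + {self.weight_rest}"
            )
        if not (0.0 <= self.trim_fraction < 1.0):
            raise DomainError(
                f"trim_fraction must be in [0, 1), got {self.trim_fraction}"
            )
        if self.trim_rule not in ("floor", "ceil"):
            raise DomainError(f"trim_rule must be 'floor' or 'ceil', got {self.trim_rule!r}")
        if self.cheapest_set_fraction is not None and not (
            0.0 < self.cheapest_set_fraction <= 1.0
        ):
            raise DomainError("cheapest_set_fraction must be in (0, 1]")
        object.__setattr__(self, "weighted_categories", frozenset(self.weighted_categories))

    def trim_count(self, n: int) -> int:
        """Number of most-expensive types to discard from a list of n."""
        k = self.trim_fraction * n
        k = math.floor(k) if self.trim_rule == "floor" else math.ceil(k)
        return min(k, n - 1)  # always retain at least one type

    def as_dict(self) -> dict:
        """Serialisable view, used for provenance in reports."""
        return {
            "weight_cheapest": self.weight_cheapest,
            "weight_rest": self.weight_rest,
            "trim_fraction": self.trim_fraction,
            "trim_rule": self.trim_rule,
            "exclude_min_from_mean": self.exclude_min_from_mean,
            "cheapest_set_fraction": self.cheapest_set_fraction,
            "weighted_categories": sorted(self.weighted_categories),
        }


DEFAULT_PRICING_POLICY = PricingPolicy()


@dataclass(frozen=True)
class HouseholdType:
    """A standardised household composition: id plus (sex, age) members."""

    id: str
    members: tuple[tuple[Sex, float], ...]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise DomainError("household must have at least one member")
        members = tuple((Sex(s), float(a)) for s, a in self.members)
        for _, age in members:
            if age <= 0:
                raise DomainError(f"member ages must be > 0, got {age}")
        object.__setattr__(self, "members", members)


#: The five reference household types all baskets are built for.
REFERENCE_HOUSEHOLDS: dict[str, HouseholdType] = {
    h.id: h
    for h in (
        HouseholdType("single_man", ((Sex.M, 40.0),)),
        HouseholdType("single_woman", ((Sex.F, 40.0),)),
        HouseholdType("couple", ((Sex.M, 40.0), (Sex.F, 40.0))),
        HouseholdType(
            "single_woman_2_children",
            ((Sex.F, 40.0), (Sex.M, 10.0), (Sex.F, 14.0)),
        ),
        HouseholdType(
            "couple_2_children",
            ((Sex.M, 40.0), (Sex.F, 40.0), (Sex.M, 10.0), (Sex.F, 14.0)),
        ),
    )
}

_SIZE_TO_BASE = {"g": 1e-3, "kg": 1.0, "mL": 1e-3, "L": 1.0}


@dataclass(frozen=True)
class ProductObservation:
    """One priced product in one shop.

    ``unit_size`` is the package size in ``unit`` (g, kg, mL or L);
    ``price_eur`` is the shelf price for that package.  ``unit_price``
    (EUR per kg or per L) is derived, never stored.  ``acceptable`` is the
    surveyor's quality flag; sales/discount prices are marked unacceptable
    upstream and never enter any price.
    """

    shop: str
    category: str
    product_type: str
    variant: str
    unit_size: float
    unit: str
    price_eur: float
    acceptable: bool = True

    def __post_init__(self) -> None:
        if self.unit not in _SIZE_TO_BASE:
            raise DomainError(f"unit must be one of g/kg/mL/L, got {self.unit!r}")
        if self.unit_size <= 0:
            raise DomainError(f"unit_size must be > 0, got {self.unit_size}")
        if self.price_eur <= 0:
            raise DomainError(f"price_eur must be > 0, got {self.price_eur}")

    @property
    def unit_price(self) -> float:
        """EUR per kg (solids) or EUR per L (liquids)."""
        return self.price_eur / (self.unit_size * _SIZE_TO_BASE[self.unit])


@dataclass(frozen=True)
class BasketItem:
    category: str
    monthly_gross_quantity: float  # g or mL per month
    unit: Unit
    pricing_mode: str  # "weighted" | "cheapest"

    def __post_init__(self) -> None:
        if self.monthly_gross_quantity < 0:
            raise DomainError("monthly_gross_quantity must be >= 0")
        if self.pricing_mode not in ("weighted", "cheapest"):
            raise DomainError(f"unknown pricing_mode {self.pricing_mode!r}")


@dataclass(frozen=True)
class FoodBasket:
    """Monthly gross purchase quantities per category for one household."""

    country: str
    household: HouseholdType
    items: tuple[BasketItem, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        cats = [it.category for it in items]
        if len(set(cats)) != len(cats):
            dupes = sorted({c for c in cats if cats.count(c) > 1})
            raise DomainError(f"duplicate basket categories: {dupes}")
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class PricedBasket:
    """A basket with unit prices, per-category monthly costs and the total."""

    basket: FoodBasket
    item_prices: Mapping[str, float]  # category -> EUR per kg or L
    item_costs: Mapping[str, float]  # category -> EUR per month
    total: float  # EUR per month

    def __post_init__(self) -> None:
        s = math.fsum(self.item_costs.values())
        if abs(s - self.total) > 1e-9:
            raise DomainError(f"total {self.total} != sum of item costs {s}")


@dataclass(frozen=True)
class IncomeReference:
    """Median equivalised disposable household income, EUR per year."""

    country: str
    median_income_eur_year: float

    def __post_init__(self) -> None:
        if self.median_income_eur_year <= 0:
            raise DomainError(
                f"income must be > 0, got {self.median_income_eur_year}"
            )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    return df


def _num(value: str, name: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise LoadError(f"row {row}: {name} {value!r} is not a number") from None


_FBDG_COLUMNS = ("country", "group", "category", "sex", "age_lo", "age_hi", "amount", "unit")


def load_fbdg(path: str | Path) -> list[FbdgEntry]:
    """Read an FBDG recommendation table; rejects rows violating invariants.

    Row numbers in error messages are 1-based over the data rows.
    """
    df = _read_csv(path, _FBDG_COLUMNS)
    out: list[FbdgEntry] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            group = FoodGroup(rec.group)
        except ValueError:
            raise LoadError(f"row {i}: unknown food group {rec.group!r}") from None
        try:
            unit = Unit(rec.unit)
        except ValueError:
            raise LoadError(f"row {i}: malformed unit {rec.unit!r} (use g or mL)") from None
        try:
            sex = Sex(rec.sex)
        except ValueError:
            raise LoadError(f"row {i}: unknown sex {rec.sex!r}") from None
        country = _check_country(rec.country, row=i)
        amount = _num(rec.amount, "amount", i)
        try:
            out.append(
                FbdgEntry(
                    country=country,
                    group=group,
                    category=rec.category,
                    sex=sex,
                    age_lo=_num(rec.age_lo, "age_lo", i),
                    age_hi=_num(rec.age_hi, "age_hi", i),
                    daily_net_amount=amount,
                    unit=unit,
                )
            )
        except DomainError as e:
            raise LoadError(f"row {i}: {e}") from None
    return out


def write_fbdg(entries: Iterable[FbdgEntry], path: str | Path) -> None:
    rows = [
        {
            "country": e.country,
            "group": e.group.value,
            "category": e.category,
            "sex": e.sex.value,
            "age_lo": e.age_lo,
            "age_hi": e.age_hi,
            "amount": e.daily_net_amount,
            "unit": e.unit.value,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=list(_FBDG_COLUMNS)).to_csv(path, index=False, encoding="utf-8")


_PRICE_COLUMNS = ("shop", "category", "product_type", "variant", "unit_size", "unit", "price_eur", "acceptable")

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_price_survey(path: str | Path) -> list[ProductObservation]:
    """Read one country's retail price survey (prices.csv schema)."""
    df = _read_csv(path, _PRICE_COLUMNS)
    out: list[ProductObservation] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        flag = _BOOL.get(str(rec.acceptable).strip().lower())
        if flag is None:
            raise LoadError(f"row {i}: acceptable {rec.acceptable!r} is not boolean")
        try:
            out.append(
                ProductObservation(
                    shop=rec.shop,
                    category=rec.category,
                    product_type=rec.product_type,
                    variant=rec.variant,
                    unit_size=_num(rec.unit_size, "unit_size", i),
                    unit=rec.unit,
                    price_eur=_num(rec.price_eur, "price_eur", i),
                    acceptable=flag,
                )
            )
        except DomainError as e:
            raise LoadError(f"row {i}: {e}") from None
    return out


def write_price_survey(obs: Iterable[ProductObservation], path: str | Path) -> None:
    rows = [
        {
            "shop": o.shop,
            "category": o.category,
            "product_type": o.product_type,
            "variant": o.variant,
            "unit_size": o.unit_size,
            "unit": o.unit,
            "price_eur": o.price_eur,
            "acceptable": o.acceptable,
        }
        for o in obs
    ]
    pd.DataFrame(rows, columns=list(_PRICE_COLUMNS)).to_csv(path, index=False, encoding="utf-8")


_INCOME_COLUMNS = ("country", "median_income_eur_year")


def load_incomes(path: str | Path) -> list[IncomeReference]:
    df = _read_csv(path, _INCOME_COLUMNS)
    out: list[IncomeReference] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        country = _check_country(rec.country, row=i)
        try:
            out.append(
                IncomeReference(
                    country=country,
                    median_income_eur_year=_num(
                        rec.median_income_eur_year, "median_income_eur_year", i
                    ),
                )
            )
        except DomainError as e:
            raise LoadError(f"row {i}: {e}") from None
    return out


def write_incomes(incomes: Iterable[IncomeReference], path: str | Path) -> None:
    rows = [
        {"country": r.country, "median_income_eur_year": r.median_income_eur_year}
        for r in incomes
    ]
    pd.DataFrame(rows, columns=list(_INCOME_COLUMNS)).to_csv(path, index=False, encoding="utf-8")


_BASKET_COLUMNS = ("country", "household_id", "category", "monthly_gross_quantity", "unit", "pricing_mode")


def write_baskets(baskets: Iterable[FoodBasket], path: str | Path) -> None:
    rows = [
        {
            "country": b.country,
            "household_id": b.household.id,
            "category": it.category,
            "monthly_gross_quantity": it.monthly_gross_quantity,
            "unit": it.unit.value,
            "pricing_mode": it.pricing_mode,
        }
        for b in baskets
        for it in b.items
    ]
    pd.DataFrame(rows, columns=list(_BASKET_COLUMNS)).to_csv(path, index=False, encoding="utf-8")


def load_basket(
    path: str | Path,
    households: Mapping[str, HouseholdType] | None = None,
) -> list[FoodBasket]:
    """Read basket.csv back into FoodBasket objects.

    Household compositions are not stored in the CSV; they are resolved by
    id against ``households`` (default: the five built-in reference types).
    """
    households = dict(households or REFERENCE_HOUSEHOLDS)
    df = _read_csv(path, _BASKET_COLUMNS)
    grouped: dict[tuple[str, str], list[BasketItem]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.household_id not in households:
            raise LoadError(f"row {i}: unknown household_id {rec.household_id!r}")
        try:
            item = BasketItem(
                category=rec.category,
                monthly_gross_quantity=_num(
                    rec.monthly_gross_quantity, "monthly_gross_quantity", i
                ),
                unit=Unit(rec.unit),
                pricing_mode=rec.pricing_mode,
            )
        except (DomainError, ValueError) as e:
            raise LoadError(f"row {i}: {e}") from None
        grouped.setdefault((rec.country, rec.household_id), []).append(item)
    return [
        FoodBasket(country=c, household=households[h], items=tuple(items))
        for (c, h), items in grouped.items()
    ]


def write_priced_baskets(priced: Iterable[PricedBasket], path: str | Path) -> None:
    """Write priced_baskets.csv: one row per item, totals repeated per basket.

    Totals and costs are reported to the cent; unit prices to 4 decimals.
    Intermediate arithmetic is never rounded — rounding happens only here.
    """
    rows = []
    for pb in priced:
        for it in pb.basket.items:
            rows.append(
                {
                    "country": pb.basket.country,
                    "household_id": pb.basket.household.id,
                    "category": it.category,
                    "unit_price": round(pb.item_prices[it.category], 4),
                    "monthly_cost": round(pb.item_costs[it.category], 2),
                    "total": round(pb.total, 2),
                }
            )
    cols = ["country", "household_id", "category", "unit_price", "monthly_cost", "total"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, encoding="utf-8")


def write_priced_baskets_json(priced: Iterable[PricedBasket], path: str | Path) -> None:
    """JSON report mirroring the PricedBasket structure, full precision."""
    payload = [
        {
            "country": pb.basket.country,
            "household_id": pb.basket.household.id,
            "items": [
                {
                    "category": it.category,
                    "monthly_gross_quantity": it.monthly_gross_quantity,
                    "unit": it.unit.value,
                    "pricing_mode": it.pricing_mode,
                    "unit_price_eur": pb.item_prices[it.category],
                    "monthly_cost_eur": pb.item_costs[it.category],
                }
                for it in pb.basket.items
            ],
            "total_eur_month": pb.total,
        }
        for pb in priced
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
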