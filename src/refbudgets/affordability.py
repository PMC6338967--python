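"""Basket cost as a share of median equivalised disposable income.

The cost of a healthy diet varies far less across countries than household
incomes do, so the interesting statistic is not the EUR/month cost itself
but that cost as a percentage of the national median equivalised disposable
income (the EU-SILC concept: household disposable income adjusted for size
and composition).  Annual incomes are converted to monthly by dividing by
12; no equivalisation arithmetic happens here — the input is already the
equivalised median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_model import DomainError, HouseholdType, IncomeReference, PricedBasket

__all__ = [
    "AffordabilityResult",
    "ComparisonReport",
    "income_share",
    "oecd_modified_scale",
    "comparison_table",
]


def oecd_modified_scale(household: HouseholdType, adult_age: float = 14.0) -> float:
    """OECD-modified equivalence factor for a household composition.

    1.0 for the first adult, 0.5 per additional member aged 14 or over,
    0.3 per child under 14.  Used to turn the per-single-adult-equivalent
    median income into the reference income of a household of this type at
    the median living standard: without it, a four-person basket compared
    against the single-adult-equivalent median would exceed 100% of income
    in low-income countries by construction.
    """
    ages = sorted((age for _, age in household.members), reverse=True)
    return 1.0 + sum(0.5 if age >= adult_age else 0.3 for age in ages[1:])


def income_share(cost: float, income: IncomeReference | float) -> float:
    """Monthly basket cost as a percentage of monthly median income.

    ``income`` is annual (EUR/year), either bare or as an IncomeReference;
    the share is 100 x cost / (income / 12).
    """
    annual = income.median_income_eur_year if isinstance(income, IncomeReference) else float(income)
    if annual <= 0:
        raise DomainError(f"income must be > 0, got {annual}")
    if cost < 0:
        raise DomainError(f"cost must be >= 0, got {cost}")
    return 100.0 * cost / (annual / 12.0)


@dataclass(frozen=True)
class AffordabilityResult:
    """One country x household affordability record.

    ``income_share`` is kept at full precision; reports round to one
    decimal place.
    """

    country: str
    household_id: str
    monthly_cost: float  # EUR/month
    monthly_income: float  # EUR/month
    income_share: float  # percent

    @classmethod
    def from_priced_basket(
        cls, priced: PricedBasket, income: IncomeReference
    ) -> "AffordabilityResult":
        """Pair a priced basket with the income of a household of this type
        at the median living standard (OECD-modified scale x the equivalised
        median); for single-adult households the scale is 1 and the share is
        plain cost over the median."""
        scale = oecd_modified_scale(priced.basket.household)
        monthly_income = scale * income.median_income_eur_year / 12.0
        return cls(
            country=priced.basket.country,
            household_id=priced.basket.household.id,
            monthly_cost=priced.total,
            monthly_income=monthly_income,
            income_share=income_share(
                priced.total, scale * income.median_income_eur_year
            ),
        )


@dataclass(frozen=True)
class ComparisonReport:
    """Cross-country comparison: sorted rows plus extreme-country statistics.

    ``cost_ratio`` is the most-expensive over the least-expensive basket
    cost among the rows.  Rankings by cost and by income share are computed
    independently — they legitimately differ whenever a cheap-basket country
    is also a low-income one.
    """

    table: pd.DataFrame
    max_cost_country: str
    min_cost_country: str
    cost_ratio: float
    max_share_country: str
    min_share_country: str

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, encoding="utf-8")

    def summary(self) -> dict:
        return {
            "max_cost_country": self.max_cost_country,
            "min_cost_country": self.min_cost_country,
            "cost_ratio": self.cost_ratio,
            "max_share_country": self.max_share_country,
            "min_share_country": self.min_share_country,
        }


def comparison_table(
    results: Sequence[AffordabilityResult],
    sort_by: str = "cost",
    non_comparable: Iterable[str] = (),
) -> ComparisonReport:
    """Assemble the cross-country comparison from affordability results.

    Rows are sorted by ``sort_by`` (``"cost"`` or ``"share"``, descending)
    with country and household id as deterministic tie-breaks, so the report
    is invariant to the input order.  Countries whose pricing procedure is
    flagged ``non_comparable`` are marked, not dropped.  Shares are rounded
    to one decimal in the table; ratio statistics use full precision.
    """
    if not results:
        raise DomainError("comparison_table needs at least one result")
    if sort_by not in ("cost", "share"):
        raise DomainError(f"sort_by must be 'cost' or 'share', got {sort_by!r}")
    non_comparable = frozenset(non_comparable)

    df = pd.DataFrame(
        [
            {
                "country": r.country,
                "household_id": r.household_id,
                "monthly_cost_eur": r.monthly_cost,
                "monthly_income_eur": r.monthly_income,
                "income_share_pct": round(r.income_share, 1),
                "non_comparable": r.country in non_comparable,
            }
            for r in results
        ]
    )
    df["cost_rank"] = df["monthly_cost_eur"].rank(ascending=False, method="min").astype(int)
    df["share_rank"] = df["income_share_pct"].rank(ascending=False, method="min").astype(int)
    key = "monthly_cost_eur" if sort_by == "cost" else "income_share_pct"
    df = df.sort_values(
        [key, "country", "household_id"], ascending=[False, True, True]
    ).reset_index(drop=True)

    max_r = max(results, key=lambda r: (r.monthly_cost, r.country))
    min_r = min(results, key=lambda r: (r.monthly_cost, r.country))
    max_s = max(results, key=lambda r: (r.income_share, r.country))
    min_s = min(results, key=lambda r: (r.income_share, r.country))
    if min_r.monthly_cost <= 0:
        ratio = math.inf if max_r.monthly_cost > 0 else 1.0
    else:
        ratio = max_r.monthly_cost / min_r.monthly_cost
    return ComparisonReport(
        table=df,
        max_cost_country=max_r.country,
        min_cost_country=min_r.country,
        cost_ratio=ratio,
        max_share_country=max_s.country,
        min_share_country=min_s.country,
    )


def plot_comparison(report: ComparisonReport, path: str | Path) -> None:
    """Dual-axis chart: bars for EUR/month, markers for % of median income."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.table
    fig, ax1 = plt.subplots(figsize=(max(6, 0.4 * len(df)), 4))
    ax1.bar(df["country"], df["monthly_cost_eur"], color="#4878a8", label="EUR/month")
    ax1.set_ylabel("Food basket, EUR/month")
    ax1.set_xlabel("Country")
    ax2 = ax1.twinx()
    ax2.plot(
        df["country"], df["income_share_pct"], "D", color="#c44e52",
        label="% of median income",
    )
    ax2.set_ylabel("% of median equivalised disposable income")
    fig.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
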