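# Methods

## The model

The pipeline computes the minimum monthly cost of a diet that follows a
country's food-based dietary guidelines (FBDG), for standardised household
types, and relates that cost to the national median equivalised disposable
income. It deliberately models only the *physical* food budget: social and
psychological functions of food, kitchen equipment, cooking energy and
physical-activity budgets are out of scope, as are currency conversion and
purchasing-power adjustment. Households are assumed to live in the capital,
shop economically among accessible retailers, prepare all meals at home, and
allocate food to each member according to that member's needs.

### From recommendation to basket

An FBDG table gives daily **net** (consumed) amounts per food category and
demographic group. For each household member the relevant entry is resolved
by a fallback ladder — exact (sex, age) match, with sex-specific entries
beating unisex ones and narrower age bands beating wider ones; then a unisex
entry covering the age; then the adult-female amounts (age 40) — because
most national guidelines are written for adults and give no child-portion
rule. The ladder is explicit, deterministic and recorded in every report.

Net amounts are converted to **gross** (purchased) amounts with per-category
waste fractions. Two conventions are supported and the choice is always a
recorded flag, never silent:

* `add_on_net` (default): gross = net × (1 + w), reading "increased with a
  waste percentage of w" literally;
* `divide_by_edible`: gross = net / (1 − w), the standard edible-portion
  accounting.

The default fractions are the six standard percentages applied uniformly
across countries: fresh fruit 0.22, fresh vegetables 0.28, potatoes 0.10,
fish 0.30 (applied to the fresh- and frozen-fish categories), fatter meat
0.20, eggs 0.12. Categories absent from the map have zero waste. Monthly
quantities use 30.4375 days (365.25/12), since "monthly" is otherwise
undefined. Basket quantities are additive over household members by
construction; the test suite asserts this composition exactly.

### Pricing

Each category is priced in EUR per kg (solids) or per L (liquids); package
prices are normalised to that denominator at load time. Two rules:

* **Lowest suitable price** for pre-packaged, low-variety categories: the
  global minimum unit price among acceptable observations. Sales/discount
  prices are excluded upstream via the `acceptable` flag.
* **Trimmed weighted price** for the fifteen large-variety categories
  (fresh/canned/pureed/frozen/dried fruit, fresh/frozen/canned vegetables,
  fresh/frozen/canned fish, lean and fat meat, charcuterie, cheese): per
  product type, take the cheapest acceptable observation; sort the per-type
  prices ascending; discard the k = ⌊0.10 · n⌋ most expensive types; the
  price is 5/7 × (cheapest retained price) + 2/7 × (mean of the other
  retained prices). With one retained type the weights collapse to its
  price. Because 5/7 + 2/7 = 1 the result always lies between the minimum
  and maximum retained price.

Where the procedure's prose admits more than one reading, the default is
declared and the alternative is a policy option:

* trim count k uses *floor* (conservative: discards less; nothing is
  discarded below ten types at the 10% trim). `trim_rule="ceil"` is offered.
* the trim applies to product *types* (kinds of fruit), not to raw shop
  observations.
* "the cheapest products" is read as the single cheapest retained per-type
  price; `cheapest_set_fraction` instead averages the bottom share of types.
* the "average of the more expensive items" is read as the average *price*,
  excluding the cheapest price (it already carries the 5/7 weight);
  `exclude_min_from_mean=False` includes it.
* per-type and global minima break price ties by lexicographic product-type
  key, for determinism across runs.

Costing is exact: cost = quantity(g or mL) / 1000 × unit price, summed with
compensated (fsum) addition; CSV reports round totals to the cent but no
intermediate value is ever rounded.

### Affordability

The share is 100 × monthly cost / (monthly reference income). The income
input is the national median *equivalised* disposable income (the EU-SILC
concept: income per single-adult equivalent); the median itself is never
recomputed. Annual-to-monthly conversion is a plain ÷12.

For a single adult the reference income is the median itself, so the
single-woman shares are directly the published statistic. For multi-person
households the median is multiplied by the household's OECD-modified
equivalence factor (first adult 1.0, each further member aged 14+ 0.5, each
child under 14 0.3; the five reference types get 1.0, 1.0, 1.5, 1.8 and
2.3): that is the disposable income a household of that composition has *at
the median living standard*. Without this scaling a four-person basket would
be divided by a one-adult-equivalent income, mechanically exceeding 100% in
low-income countries and comparing incomparable quantities. The factor used
is recorded in every result row via the reported monthly income.

Rankings by cost and by share are
computed independently — a cheap-basket country can still have the highest
share when its income is low, and the comparison report preserves both
orders. Countries whose pricing procedure is known not to be comparable can
be flagged; they are marked in the report, never dropped. Shares are
reported to one decimal place; ratio statistics use full precision.

## Synthetic data

No national price survey or FBDG table is distributed, so the generators
emulate the *structure* of all three inputs, never any country's actual
content:

* **FBDG**: per (country, food group, demographic band), a daily amount is
  drawn uniformly inside the spans observed across the 26 national
  guidelines — fruit and vegetables 300–400 g each, dairy 215–710 g,
  meat/fish/eggs 90–339 g, residual 25–155 g — plus ranges a nutritionist
  would call typical where no span is documented (grains 200–350 g, fats
  20–60 g, liquids 1500–2500 mL). The group amount is split into purchasable
  categories with fixed shares so that both pricing rules and all six waste
  fractions are exercised end to end. Three demographic bands are generated
  (adult F, adult M, unisex child), exercising the fallback ladder for the
  10-year-old boy and 14-year-old girl of the reference households.
* **Prices**: per category, product type and shop, price = country
  multiplier × Lognormal(log(base price), σ = 0.35). The lognormal gives the
  right skew of real shelves — many cheap staples, few expensive variants —
  so the 10% trim actually bites. About 5% of observations are flagged
  unacceptable. Base prices are realistic EUR/kg medians (potatoes 0.9,
  fresh fish 9.0, ...).
* **Incomes**: log-uniform in 2 400–40 000 EUR/year, the EU-like spread
  between the poorest and richest national medians; the log scale reflects
  that incomes are ratio-scale and that national medians cluster towards the
  low end of the span. The default country price
  multipliers increase linearly with income over 0.75–1.5, reproducing the
  empirical compression: price levels span a factor of two while incomes
  span more than ten, which is why income shares vary across countries far
  more than basket costs do.

Randomness is keyed per entity: every generator derives an independent
substream from (seed, kind, country or category) via CRC-32 keys fed to
NumPy's `SeedSequence`, so adding a country or category never perturbs any
other draw. The price *structure* (the lognormal draws and quality flags) is
keyed by category only and shared across countries; country levels enter
purely through the multiplier. That makes cross-country cost differences
exactly proportional to the multipliers — a controlled setting in which
scale-equivariance of the whole pipeline can be asserted to machine
precision, at the cost of unrealistically identical relative price
structures across countries.

What passing tests on these inputs do **not** show: anything about real
national price levels, real guideline contents, seasonal or within-city
price variation, or correlated quality and price. The generators exist to
verify the pipeline's arithmetic and invariants, not to estimate any
country's actual figures.

## Numerical choices and degenerate inputs

* 5/7 and 2/7 are exact binary-float neighbours whose sum is exactly 1.0;
  the policy constructor enforces the normalisation to 1e-12.
* Weighted pricing keeps at least one type regardless of the trim; an empty
  price list, an unsorted list, or a category with no acceptable
  observations raises a pricing error (unpriceable categories are collected
  and reported together per basket).
* Waste fractions live in [0, 1); 1.0 would mean purchasing infinitely much
  and is rejected.
* A priced basket validates total = Σ item costs to 1e-9 at construction.
* Zero-cost baskets give a 0% share; non-positive incomes are rejected.
* Table loaders report the 1-based data-row number of the first invalid row;
  country codes outside the 26 pilot codes warn but load.

## Problem sizes

The default end-to-end run generates 26 countries × 5 household types
(130 baskets), with 10 product types × 4 shops per category in each survey;
the pricing-oracle cross-check enumerates all 43 757 sorted price lists of
length 1–8 on a 0.5-step grid, and the monotonicity suite runs 1 000
randomized single-price perturbations. The full test suite and the
acceptance script each complete in a few seconds.

## Known limitations

* The demographic fallback ladder is this package's convention; the source
  methodology never specifies how children's amounts derive from
  adult-oriented guidelines.
* One basket item per category: weekly menus, recipes and product-level
  shopping lists are out of scope.
* Shop-selection criteria (accessibility, spread over the city) are survey
  metadata, not computation.
* The deviating national pricing procedures that made two countries' results
  "not fully comparable" are undocumented and not modelled; the comparison
  report can only flag such countries.
* No nutrient-level validation: a basket that satisfies the guideline
  amounts is taken as healthy by definition.
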