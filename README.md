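# ons-exchanges

A toolkit for dietitians and clinical-nutrition researchers that converts
**oral nutritional supplements (ONSs)** — sip feeds, puddings, powders used
to treat malnutrition — into **diabetic food exchanges**, so that a
supplement can be dropped into an exchange-based meal plan the same way a
food portion would be.

## What it computes

**Exchange conversion.** A food exchange is a standardized portion
contributing roughly fixed macronutrients: one *starch* exchange ≈ 15 g
carbohydrate (80 kcal), one *lean-meat* exchange ≈ 7 g protein + 3 g fat
(55 kcal), one *fat* exchange ≈ 5 g fat (45 kcal). Per serving of product,
the engine applies banded gram ranges: e.g. 1–5 g carbohydrate → no starch
exchange, 6–10 g → ½, 11–20 g → 1, extended periodically (period 15 g)
above the printed ranges; protein < 4 g → 0, 4 g to just under 14 g → 1,
then ⌊g/7⌋; fat < 2 g → 0, 2–4 g → ½, 4–7 g → 1, extended with period 5 g.
When a serving declares more than 5 g of fiber, only half the fiber grams
count toward carbohydrate. Starch and fat come in half-units, lean meat in
whole units.

**Categorization.** Liquid products are classed by energy density *d* =
kcal/mL: low (*d* < 1.0), normal/isocaloric (1.0 ≤ *d* ≤ 1.2), high
(*d* > 1.2); and as high-protein when protein supplies > 20 % of energy
(4 kcal/g). Composite labels (high-energy–high-protein,
high-energy–normal-protein) follow.

**Database layer.** CSV/TSV product tables (per-serving energy and
macronutrient grams) are validated row by row — decimal commas normalized,
energy checked against the Atwater reconstruction 4·C + 4·P + 9·F — and
annotated with exchanges and labels.

**Meal planning.** Exchange-count plans are totalled with a per-exchange
composition table; incorporating an ONS subtracts its exchange set from the
matching food groups and adds its label macronutrients back, with
weight-based energy (30 kcal/kg band) and protein (≥ 1 g/kg floor) target
checks.

**Category statistics.** Median/IQR summaries per category (liquids
serving > 500 mL excluded), Mann–Whitney comparisons against the
isocaloric group, and Spearman correlations between macronutrient grams
and computed exchanges.

A synthetic-database generator (`ons_exchanges.synthetic`) emulates the
structure of commercial ONS catalogs — serving volumes, energy-density and
protein-fraction mixtures, powders — without fabricating brand data.

## Worked example

Two 200-mL servings of a high-energy supplement containing 36.8 g
carbohydrate, 11.8 g protein and 11.6 g fat per serving:

```console
$ ons-exchanges exchanges --cho 36.8 --protein 11.8 --fat 11.6 --servings 2
starch: 5
lean meat: 2
fat: 4
```

Incorporating those two servings into a 2100-kcal exchange plan for a
70-kg older adult (the base plan totals 234 g carbohydrate, 94 g protein,
81 g fat, 2075 kcal):

```console
$ ons-exchanges plan --milk-medium-fat 2 --fruit 3 --vegetables 3 \
    --starch 10 --lean-meat 6 --fat 10 \
    --ons-cho 36.8 --ons-protein 11.8 --ons-fat 11.6 --ons-servings 2 \
    --body-mass 70
ONS exchanges (2 serving(s)): starch 5, lean meat 2, fat 4
final food exchanges (initial - ONS):
  milk_medium_fat: 2
  fruit: 3
  vegetables: 3
  starch: 5
  lean_meat: 4
  fat: 6
totals: 232.6 g carbohydrate, 88.6 g protein, 76.7 g fat, 1982.6 kcal
energy target 2100 kcal: NOT met
protein target 70 g: met
```

The supplement replaces 5 starch, 2 lean-meat and 4 fat exchanges of food.
Because its label macronutrients (597.6 kcal Atwater) sit slightly below
the 690 kcal of the exchanges it displaces, the combined plan lands about
4½ % under the food-only plan — within the exchange system's usual
approximation, but just outside the strict ±5 % band against the 2100-kcal
target, which the report states plainly rather than rounding away.

Other subcommands: `annotate` (database → exchanges + labels), `summarize`
(median/IQR per category), `correlate` (Spearman matrix), `generate`
(synthetic database CSV). `--rules` and `--composition` accept
`key = value` files overriding the band tables and the per-exchange
composition.

## Caveats

Exchange assignments are per-serving conveniences for plan building, not a
substitute for product-level dietetic judgment: intra-category spread is
large, micronutrients and carbohydrate quality are out of scope, and plans
should be individualized by a professional.
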