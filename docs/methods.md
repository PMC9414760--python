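# Methods

## The exchange model

The toolkit treats a food exchange as a fixed macronutrient quantum:
15 g carbohydrate per starch exchange, 7 g protein per lean-meat exchange,
5 g fat per fat exchange. ONS servings are mapped to exchange counts by
banded lookup rather than by division, reflecting how exchange lists are
used at the desk: a serving with 11–20 g of carbohydrate *is* one starch
exchange, not 0.73–1.33 of one.

### Band tables and their extension

The published ranges only cover small amounts. The engine extends them with
the **minimal periodic extension** consistent with a two-can worked example
(36.8 g carbohydrate → 2.5 starch, 11.8 g protein → 1 lean meat, 11.6 g
fat → 2 fat per serving):

* **Starch** — [0, 5.5) → 0; [5.5, 10.5) → ½; for k ≥ 1,
  [15k − 4.5, 15k + 5.5) → k and [15k + 5.5, 15k + 10.5) → k + ½.
  Whole-exchange bands of width 10 g centred on multiples of 15 g,
  half-exchange bands of width 5 g between them. The printed ranges leave
  gram gaps (5–6 g, 10–11 g); these are closed at the midpoints (5.5,
  10.5, …) so non-integer label values are handled.
* **Lean meat** — 0 below 4 g; 1 from 4 g to just under 14 g; ⌊g/7⌋ from
  14 g. Protein exchanges are whole units only (half protein exchanges are
  never reported in practice), and the single-exchange band is wider than
  the printed "4–10 g" because 11.8 g must map to 1.
* **Fat** — [0, 2) → 0; [2, 4) → ½; for k ≥ 1, [5k − 1, 5k + 2] → k
  (closed) and (5k + 2, 5k + 4) → k + ½. The printed half- and
  whole-exchange ranges overlap at exactly 4 g; the whole exchange wins.
  A side effect of the closed whole-band tops: the periodicity identity
  fat(g + 5) = fat(g) + 1 holds for every g strictly above 2 g but fails
  at the single point g = 2 (fat(2) = ½, fat(7) = 1).

Each band family partitions [0, ∞), is non-decreasing, and emits
half-units (starch, fat) or integers (lean meat). The test suite checks
these properties and compares the closed-form lookups against an
independent boundary-list scan on a 0.1 g grid from 0 to 200 g.

**Fiber rule.** When fiber exceeds 5 g per serving, half of the fiber
grams are subtracted from carbohydrate before the starch lookup (floored
at zero, with a warning, for labels declaring more fiber than
carbohydrate). At or below 5 g fiber changes nothing.

**Servings.** Bands apply per serving, then scale linearly. Fractional
servings are allowed; the half-unit granularity invariant is only asserted
for integral serving counts.

An alternative parameterization in which starch-associated protein and fat
are subtracted before the meat/fat lookups (as in some label-conversion
protocols) was considered and rejected: no such subtraction scheme was
found that reproduces the worked example, while the direct bands reproduce
it exactly.

## Categorization

Energy density uses the liquid serving volume; 1.0 and 1.2 kcal/mL both
belong to "normal" (the neighboring classes are defined by strict
inequalities). Protein energy uses the Atwater factor 4 kcal/g — the
conventional choice; the cutoff source does not state a factor. "Normal
protein" means simply *not* high-protein (≤ 20 % of energy). Powders get
no energy category rather than a per-100-g surrogate, because the cutoffs
are defined per milliliter of ready-to-drink product; they keep the
protein-based label. Low-energy liquids fall outside all five category
labels, which cover only normal- and high-energy products.

## Meal-plan arithmetic

The default per-exchange composition table (medium-fat milk 12/8/5 g and
120 kcal; fruit 15/0/0, 60; vegetables 5/2/0, 25; starch 15/3/0.3, 80;
lean meat 0/7/3, 55; fat 0/0/5, 45) is derived by dividing a published
2100-kcal plan's row totals by its exchange counts. Groups whose values
could not be derived that way (non-fat/whole milk, very-lean/medium-fat/
high-fat meat) are deliberately absent from the default table — users
supply them via the composition config rather than the package inventing
values.

Incorporation subtracts the supplement's exchange set from the matching
food groups (clamping at zero with a warning) and attaches the supplement;
plan totals count the supplement by its **label grams**, not its
exchange-implied grams, since the label is the ground truth and exchanges
its half-unit approximation. The energy target is a two-sided ±5 % band
around mass × 30 kcal/kg; the protein target is an inclusive floor at
mass × 1 g/kg. Defaults follow standard recommendations for older adults
and are all overridable.

## Category statistics

Label data are skewed, so summaries are median + IQR with quartiles by
linear interpolation between order statistics (numpy's default; stated
here because quartile conventions differ). Liquids serving more than
500 mL are excluded from all statistics to keep portions comparable
(typical servings are 130–300 mL); both pre- and post-exclusion counts are
reported. Group comparisons use the two-sided Mann–Whitney U — exact
enumeration when both groups have ≤ 20 tie-free observations, otherwise
the normal approximation with tie and continuity correction. Correlations
are tie-corrected Spearman. No multiple-testing correction is applied;
each p-value is read against 0.05 on its own. A Kolmogorov–Smirnov
normality diagnostic is provided as a pass-through check only — it gates
nothing, since the pipeline is nonparametric throughout.

## Synthetic databases

The generator emulates the *structure* of commercial ONS catalogs, not any
real catalog's distribution: archetype mixture (isocaloric 30 %,
high-energy–normal-protein 25 %, high-energy–high-protein 25 %,
high-protein 12 %, powder 8 % by default — roughly the proportions seen in
published catalogs), liquid servings uniform on 125–330 mL with a 4 %
rate of > 500 mL outliers (exercising the volume exclusion), energy
densities drawn inside each category band with a margin (normal
1.05–1.14, high 1.30–2.30, low 0.70–0.95 kcal/mL), protein-energy
fractions 8–18 % (normal) or 23–38 % (high), fiber on 35 % of products
(1–8 g), fat as the energy remainder after carbohydrate (40–62 % of
energy) and protein. Macronutrient grams are generated Atwater-consistent
and the *declared* energy is then jittered ±4 % around the reconstruction,
as on real labels; the margins are wider than the jitter, so each
archetype classifies back to its own labels (the round-trip rate is
asserted at ≥ 95 % and is in practice 100 %). Powders draw gram servings
at 3.6–4.4 kcal/g so macronutrient mass stays below serving mass.

What this does **not** emulate: real catalogs' correlated marketing
niches, diabetes-specific carbohydrate profiles, fiber–category
associations, or any brand's actual values. Passing statistical tests on
synthetic databases therefore demonstrates internal consistency of the
pipeline (e.g. that each exchange type correlates most with its own
macronutrient), not agreement with any published catalog's numbers —
which would require the catalog itself, loadable via
`database_io.read_product_spreadsheet`.

## Numerical and I/O choices

* Band boundaries use half-open intervals except the fat whole-exchange
  tops (closed, see above); boundaries are representable binary fractions
  (x.5), so grid tests hit them exactly.
* Exchange granularity is validated with a 1e-9 tolerance relative to the
  half-unit grid.
* Canonical persistence is delimited text (diff-able, testable); grams are
  written with one decimal, kcal as integers, and read(write(x)) = x holds
  at that precision. A spreadsheet mirror (no formulas, no locked cells)
  is provided for interoperability with spreadsheet-based workflows.
* The Atwater energy-consistency check warns at 15 % relative mismatch —
  generous because fiber fermentation and polyols make the 4/4/9
  reconstruction inexact — and never rejects a row.
* Validation is total: malformed rows are reported with row/field/message
  and skipped; only a missing required column aborts a read.

## Problem sizes

The statistical property tests run on a seed-fixed 400-product synthetic
database, with 1000 label permutations for the rank-sum type-I-error check
and a 0.1 g × 200 g grid (2001 points per macronutrient) for the band
oracle comparison; these sizes make the full suite run in seconds while
leaving the asymptotic approximations well inside their comfort zone.

## Known limitations

* Exchange assignment ignores carbohydrate quality (maltodextrin vs
  lactose), micronutrients and immunonutrients; two products with equal
  exchanges can differ clinically.
* Milk exchanges are deliberately not used for ONSs (most are
  lactose-free and maltodextrin-based), so ONS exchanges are expressed in
  starch/lean-meat/fat only.
* The band extension above the printed gram ranges is an interpolation
  choice anchored on a single worked example; other periodic extensions
  are conceivable.
* Category statistics on synthetic data are qualitative checks only (see
  above).
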