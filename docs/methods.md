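# Methods

## Model

A national food-based dietary guideline (FBDG) is a set of daily
quantitative recommendations, one per food group, designed for a stated
energy level. Its carbon footprint is the sum over groups of the
recommended amount times the consumption-weighted emission intensity of
the group:

    GHGE_g = Σ_c REC_g · Proportion_c · CF_c · GHGE_c
    total  = ( Σ_g GHGE_g + sugar term ) · diet_kcal / (diet_kcal − discretionary_kcal)

with, per commodity *c* in group *g*:

* `Proportion_c` — the commodity's share of the group's cooked-edible
  apparent consumption, derived from balance-sheet supply data
  (kg/capita/year). Apparent consumption is supply available for human
  consumption, a proxy for intake, not measured intake.
* `CF_c` — composite conversion from one recommendation unit to kilograms
  of raw edible commodity: the unit→kg(consumed) factor (mass identity,
  28.3495 g/oz, density for ml, calorie equivalence for cups) times a
  cooked→raw adjustment, because recommendations refer to food as
  consumed while intensities refer to raw edible mass.
* `GHGE_c` — cradle-to-farm-gate emission intensity, kg CO₂-eq per kg raw
  edible food, one global table for all countries (country-resolved
  intensities are not available at commodity coverage).

Key assumptions: within a group, recommended mass is distributed across
commodities exactly in proportion to national supply; discretionary
calories (energy the guideline leaves unspecified) have the same emission
intensity per kcal as the rest of the recommended diet; one "piece" of
fruit equals one cup; milk-type dairy density is 1.0305 g/ml.

## Normalization of guidelines

Range recommendations collapse to their midpoint. Guidelines stated at
other energy levels scale pro-rata (all amounts, subgroup amounts and the
discretionary allowance multiply by `target/diet_kcal`); scaling is
homogeneous of degree one and path-independent. `serving` units are
rejected at load time — serving sizes are country-specific, so configs
must resolve them to g/ml/cup. Guideline configs are data files, one
country each; nothing about a specific country lives in code.

## Consumption patterns

Supply records carry a processing state (`carcass`, `raw_in_shell`,
`raw_edible`, `dry_raw`, `as_is`). The state implies a default conversion
chain to cooked edible mass (carcass → boning → cooking; in-shell →
shelling → cooking; dry → cooking; as-is → identity), overridable per row
with an explicit `conversion_chain` column. Factors ship as an editable
CSV of `{commodity, step, factor, direction}`; the declared direction
(gain/loss) is validated, never guessed from the commodity name, and
`raw_to_cooked` factors for meats are understood as the average of dry-
and wet-method cooking factors.

Commodities with no emission-intensity entry cannot enter the footprint
sum. They are excluded **before** proportions are taken, so shares always
form a proper distribution over usable commodities; the excluded mass
fraction is recorded on the pattern and written to the audit log. (In the
reference analysis the excluded commodities contribute trivially — under
10 kcal/capita/day — so ordering matters little, but renormalization keeps
the weighted average well-defined in general.)

The engine's cooked→raw factors are the reciprocals of the data file's
raw→cooked / dry→cooked factors: a meat keeping 72% of its mass when
cooked needs 1/0.72 kg raw per cooked kg; a grain cooking up 2.2× from
dry needs 1/2.2. Commodities without a cooking factor (produce, dairy,
oils, sugar) default to identity: their intensity basis matches the
consumed state.

## Totals, sugar, discretionary calories, controlled comparison

A fixed sugar/sweetener amount is modelled as a one-commodity group
(intensity under the `sugar & sweeteners` label) added to the base total
**before** the discretionary gross-up. The ordering is a convention: in
the reference data the sugar term is < 0.02 kg CO₂-eq/d, so the ordering
is immaterial at display precision, and applying the gross-up last keeps
"total ≥ base_total" exact.

The controlled comparison evaluates every guideline under one reference
country's patterns, restricting and renormalizing to each guideline's
allowed-commodity lists where present (e.g. a plant-proteins-only protein
group). The ratio column is computed from full-precision totals and
rounded only for display; evaluating the reference country under its own
pattern is the same code path as the baseline, so its row matches to
machine precision.

## Numerical and display choices

* Internal canonical units: kg and kcal; full precision end to end.
* Display rounding mirrors conventional reporting: 3 decimals in worked
  examples, 2 decimals in country tables and totals.
* Computed pattern shares sum to 1 within 1e-9. The
  `ConsumptionPattern` constructor accepts a 0.005 absolute tolerance on
  the sum so that patterns transcribed from tables printed at 3 decimal
  places validate (the packaged worked example's printed proportions sum
  to 1.001).
* Lookup failure in any factor table is an explicit error naming the
  commodity and the table, never a silent zero.
* Output CSVs use fixed row/column ordering (input config order) and
  explicit float formatting, so identical inputs give byte-identical
  files.

## Synthetic data generator

The generator emulates the *structure* of the study inputs, not any real
country: per country×group, cooked-edible shares are symmetric
Dirichlet(`share_concentration`) (proportions on a simplex), group totals
are lognormal around magnitudes typical of balance sheets, supply masses
are backed out through each commodity's conversion chain, and intensities
are lognormal (log-sd 0.8 about a median of 1 kg CO₂-eq/kg — strictly
positive and right-skewed, the qualitative shape of food LCA data).
Synthetic guideline amounts are drawn uniformly within the ranges spanned
by published 2000-kcal guidelines (e.g. protein 75–170 g/d, dairy 118–710
ml/d). All generators are pure functions of `(config, seed)` and their
output passes the same schema validation as user files.

What passing tests on synthetic data show: the arithmetic chain — state
conversion, exclusion, normalization, weighting, gross-up, controlled
substitution — is correct and deterministic. What they do not show:
anything about real supply compositions, real conversion factors, or real
intensities; those enter only through user-supplied data files, and the
packaged worked example pins the engine to one published reference
calculation.

## Problem sizes

The test suite and the acceptance script run on the packaged worked
example (10 commodities), printed reference tables (9 guideline sets × 6
groups), 100-instance randomized oracle comparisons, and synthetic bundles
of 2–3 countries × 4–6 commodities per group — sizes chosen because the
model is exactly linear, so correctness does not improve with scale.

## Known limitations

* Single impact category (GHGE), cradle-to-farm-gate boundary; land and
  water use, processing, transport and preparation are out of scope.
* Apparent consumption overstates intake (waste is included) and one
  global intensity table ignores country-level production differences.
* No uncertainty propagation: intensities are point means.
* Subgroup amounts within a recommendation are validated and rescaled but
  the engine distributes the group total by consumption shares (restricted
  to allowed commodities where given); fixed subgroup splits are honored
  by encoding them as separate restricted patterns in user data.
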