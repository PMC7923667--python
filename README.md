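# dietfootprint

Carbon footprint modelling of national food-based dietary guidelines
(FBDG), for nutrition and food-system researchers who want to compare the
greenhouse-gas implications of what countries *recommend* people eat —
separately from what people currently eat.

National guidelines state daily amounts per food *group* ("156 g of
protein foods") but never per food *item*, and emission intensities differ
by an order of magnitude between items within a group (beef vs. beans).
This package closes that gap the way footprint analysts do in practice:

1. **Normalize the guidelines.** Ranges collapse to midpoints, patterns
   stated at other energy levels are rescaled pro-rata to 2000 kcal, and
   heterogeneous units (oz, cups, "pieces", ml) resolve to mass via
   standard factors and calorie equivalence.
2. **Give groups item-level specificity.** Within each group, a country's
   apparent-consumption proportions are derived from food-balance-sheet
   supply data (kg/capita/year), after converting every commodity to a
   common cooked-edible mass basis (carcass → boneless → cooked for meats,
   shelled for nuts and eggs, dry → cooked for grains and legumes).
3. **Compute emissions.** For each group *g* with recommended amount
   `REC_g`:

   ```
   GHGE_g = Σ_c  REC_g · Proportion_c · CF_c · GHGE_c
   ```

   where `Proportion_c` is commodity *c*'s within-group consumption share,
   `CF_c` converts one recommendation unit to kg of raw edible commodity,
   and `GHGE_c` is its cradle-to-farm-gate intensity (kg CO₂-eq/kg).
   Group values sum to a diet total; fixed sugar add-ons enter as a
   single-commodity group, and discretionary calories (energy with
   unspecified composition) gross the total up pro-rata:
   `total = base · diet_kcal / (diet_kcal − discretionary_kcal)`.
4. **Control for consumption patterns.** Because step 2 bakes each
   country's current diet into its result, a *controlled comparison*
   re-evaluates every guideline under one fixed reference country's
   pattern, so remaining differences reflect the recommendations alone.

## Worked example

The package ships the published US fruit worked example — 2 cups/day
spread over ten balance-sheet fruit commodities with their consumption
proportions, cup→kg factors and emission intensities:

```python
from dietfootprint import table2_fixture, group_footprint, apply_discretionary

fx = table2_fixture()
total, contribs = group_footprint(fx.rec.amount, fx.pattern, fx.conversions, fx.impacts)
print(f"US fruit recommendation (2 cups/d): {total:.3f} kg CO2-eq/d")
for c in ("oranges, tangerines, mandarins, & products", "bananas"):
    print(f"  {c}: {contribs[c]:.3f} kg CO2-eq/d")
print(f"US diet total after discretionary allocation: "
      f"{apply_discretionary(3.31, 270, 2000):.2f} kg CO2-eq/d")
```

prints

```
US fruit recommendation (2 cups/d): 0.165 kg CO2-eq/d
  oranges, tangerines, mandarins, & products: 0.030 kg CO2-eq/d
  bananas: 0.013 kg CO2-eq/d
US diet total after discretionary allocation: 3.83 kg CO2-eq/d
```

The 0.165 is the consumption-weighted emission cost of meeting the fruit
recommendation; oranges dominate because they combine a large share with a
mid-range intensity.  The 3.83 is the full US diet total: the six
per-group values sum to 3.31 kg CO₂-eq/d, grossed up for the 270
discretionary kcal of the 2000-kcal pattern.

Nine transcribed guideline sets (seven countries, a vegetarian variant,
and the EAT-Lancet reference diet, all on a 2000-kcal basis) are available
via `dietfootprint.packaged_guidelines()`.

## Command line

`dietfootprint synth` emits a complete synthetic study bundle (supply,
dairy, impacts, conversions, composition, guidelines); `baseline` and
`controlled` run the two analyses on any bundle; `validate` schema-checks
inputs.

```bash
dietfootprint synth --out-dir demo --seed 7 --n-countries 3 --commodities-per-group 4
dietfootprint baseline --guidelines demo/guidelines --supply demo/supply.csv \
    --dairy demo/dairy.csv --impacts demo/impacts.csv \
    --conversions demo/conversions.csv --out-dir demo_out
```

```
     country  protein_foods  dairy  grains  fruit  vegetables  oils_fats  sugar  total
synthland_01           0.12   0.52    0.14   0.25        0.63       0.14    0.0   2.09
synthland_02           0.09   0.77    0.30   0.56        0.43       0.04    0.0   2.20
synthland_03           0.14   0.27    0.21   2.78        0.62       0.15    0.0   4.92
```

Columns are kg CO₂-eq/day per food group; `controlled` adds a
`reference_ratio` column (reference country's total ÷ row total).  Output
CSVs are byte-identical across re-runs with the same inputs.

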