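country: United States
diet_kcal: 2000
discretionary_kcal: 270
notes: >-
  Fruit is recommended as 2 cups/d, transcribed here in grams after
  calorie-equivalence conversion. Discretionary calories are allocated
  pro-rata over the rest of the diet.
recommendations:
- {group: protein_foods, amount: 156, unit: g}
- {group: dairy, amount: 710, unit: ml}
- {group: grains, amount: 170, unit: g}
- {group: fruit, amount: 392, unit: g}
- {group: vegetables, amount: 350, unit: g}
- {group: oils_fats, amount: 27, unit: g}
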