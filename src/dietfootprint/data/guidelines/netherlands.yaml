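country: The Netherlands
diet_kcal: 2000
discretionary_kcal: 308
notes: >-
  Scaled from the 2053-kcal main pattern. Grains include potatoes.
  Discretionary calories are allocated pro-rata over the rest of the diet.
recommendations:
- {group: protein_foods, amount: 150, unit: g}
- {group: dairy, amount: 415, unit: ml}
- {group: grains, amount: 428, unit: g}
- {group: fruit, amount: 200, unit: g}
- {group: vegetables, amount: 250, unit: g}
- {group: oils_fats, amount: 40, unit: g}
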