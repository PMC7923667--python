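country: US Vegetarian
diet_kcal: 2000
discretionary_kcal: 290
notes: >-
  Protein group restricted to plant proteins and eggs; the allowed-commodity
  list uses balance-sheet item labels and is editable to match the supply
  vocabulary.
recommendations:
- group: protein_foods
  amount: 97
  unit: g
  allowed_commodities: [beans, peas, pulses other and products, soyabeans,
                        nuts and products, eggs]
- {group: dairy, amount: 710, unit: ml}
- {group: grains, amount: 184, unit: g}
- {group: fruit, amount: 392, unit: g}
- {group: vegetables, amount: 350, unit: g}
- {group: oils_fats, amount: 27, unit: g}
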