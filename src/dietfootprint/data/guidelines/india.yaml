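country: India
diet_kcal: 2000
notes: >-
  Protein recommendation covers pulses only; the allowed-commodity list uses
  balance-sheet item labels and is editable to match the supply vocabulary.
  Sugar carries a fixed 30 g/d add-on.
recommendations:
- group: protein_foods
  amount: 75
  unit: g
  allowed_commodities: [beans, peas, pulses other and products]
- {group: dairy, amount: 300, unit: ml}
- {group: grains, amount: 330, unit: g}
- {group: fruit, amount: 100, unit: g}
- {group: vegetables, amount: 500, unit: g}
- {group: oils_fats, amount: 25, unit: g}
- {group: sugar, amount: 30, unit: g}
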