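country: Uruguay
diet_kcal: 2000
notes: >-
  Scaled from the 2200-kcal main pattern. Fruit and vegetables form a single
  combined group. Protein covers eggs, fish and seafood, and meat. Sugar
  carries a fixed 60 g/d add-on.
recommendations:
- {group: protein_foods, amount: 91, unit: g}
- {group: dairy, amount: 455, unit: ml}
- {group: grains, amount: 227, unit: g}
- {group: fruit_and_vegetables, amount: 455, unit: g}
- {group: oils_fats, amount: 25, unit: g}
- {group: sugar, amount: 60, unit: g}
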