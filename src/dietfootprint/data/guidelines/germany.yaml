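country: Germany
diet_kcal: 2000
notes: >-
  Dairy stated by volume; sugar/sweeteners carry a fixed 32 g/d add-on.
  Protein group covers animal proteins only.
recommendations:
- {group: protein_foods, amount: 99, unit: g}
- {group: dairy, amount: 524, unit: ml}
- {group: grains, amount: 362, unit: g}
- {group: fruit, amount: 250, unit: g}
- {group: vegetables, amount: 512, unit: g}
- {group: oils_fats, amount: 35, unit: g}
- {group: sugar, amount: 32, unit: g}
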