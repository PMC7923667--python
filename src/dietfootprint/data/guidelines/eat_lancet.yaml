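country: EAT-Lancet
diet_kcal: 2000
notes: >-
  Global reference diet, scaled from the 2500-kcal pattern. Evaluated under
  the US apparent-consumption pattern by convention.
recommendations:
- {group: protein_foods, amount: 167, unit: g}
- {group: dairy, amount: 194, unit: ml}
- {group: grains, amount: 186, unit: g}
- {group: fruit, amount: 160, unit: g}
- {group: vegetables, amount: 280, unit: g}
- {group: oils_fats, amount: 42, unit: g}
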