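country: Oman
diet_kcal: 2000
notes: Grains include potatoes.
recommendations:
- {group: protein_foods, amount: 168, unit: g}
- {group: dairy, amount: 118, unit: ml}
- {group: grains, amount: 662, unit: g}
- {group: fruit, amount: 686, unit: g}
- {group: vegetables, amount: 420, unit: g}
- {group: oils_fats, amount: 56, unit: g}
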