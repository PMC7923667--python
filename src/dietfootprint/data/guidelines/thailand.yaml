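country: Thailand
diet_kcal: 2000
notes: >-
  Grains include roots and tubers. No oils/fats recommendation is made.
  Fruit was stated in "pieces" (one piece taken as one cup) and is
  transcribed here already resolved to grams.
recommendations:
- {group: protein_foods, amount: 135, unit: g}
- {group: dairy, amount: 237, unit: ml}
- {group: grains, amount: 600, unit: g}
- {group: fruit, amount: 784, unit: g}
- {group: vegetables, amount: 200, unit: g}
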