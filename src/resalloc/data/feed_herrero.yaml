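# Herrero-style feed conversion table: FCR (kg dry-matter feed per kg
# protein, herd level) and CRFF (crop-residue fraction of the diet by
# weight), keyed by region / animal {cattle, sheep_goat} / production system
# {grazing, mixed, intensive, other} / climate {arid, temperate, tropical} /
# product {meat, milk}.
#
# The published source tabulates ten world regions; the values below are
# representative magnitudes for the default region plus two contrasting
# regions, intended as editable placeholders for real-data runs.  Missing
# (system, climate) combinations resolve through the "any" fallbacks.
fcr:
  - {animal: cattle, product: meat, value: 350}
  - {animal: cattle, product: meat, system: grazing, value: 520}
  - {animal: cattle, product: meat, system: mixed, value: 300}
  - {animal: cattle, product: meat, system: intensive, value: 190}
  - {animal: cattle, product: milk, value: 90}
  - {animal: cattle, product: milk, system: grazing, value: 130}
  - {animal: cattle, product: milk, system: mixed, value: 80}
  - {animal: cattle, product: milk, system: intensive, value: 55}
  - {animal: sheep_goat, product: meat, value: 420}
  - {animal: sheep_goat, product: meat, system: grazing, value: 560}
  - {animal: sheep_goat, product: meat, system: mixed, value: 360}
  - {animal: sheep_goat, product: milk, value: 110}
  - {region: tropical_smallholder, animal: cattle, product: meat, value: 480}
  - {region: tropical_smallholder, animal: cattle, product: milk, value: 120}
  - {region: temperate_industrial, animal: cattle, product: meat, value: 240}
  - {region: temperate_industrial, animal: cattle, product: milk, value: 65}
crff:
  - {animal: cattle, product: meat, value: 0.25}
  - {animal: cattle, product: meat, system: grazing, value: 0.10}
  - {animal: cattle, product: meat, system: mixed, value: 0.40}
  - {animal: cattle, product: meat, system: mixed, climate: arid, value: 0.50}
  - {animal: cattle, product: meat, system: intensive, value: 0.15}
  - {animal: cattle, product: milk, value: 0.25}
  - {animal: cattle, product: milk, system: grazing, value: 0.10}
  - {animal: cattle, product: milk, system: mixed, value: 0.35}
  - {animal: sheep_goat, product: meat, value: 0.20}
  - {animal: sheep_goat, product: meat, system: grazing, value: 0.08}
  - {animal: sheep_goat, product: meat, system: mixed, value: 0.30}
  - {animal: sheep_goat, product: milk, value: 0.20}
  - {region: tropical_smallholder, animal: cattle, product: meat, value: 0.45}
  - {region: temperate_industrial, animal: cattle, product: meat, value: 0.08}
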