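# Mekonnen-style feed conversion table: FCRs by region / animal / system
# (grazing, mixed, industrial -> canonical "intensive").  This source
# publishes no crop-residue feed fractions; the loader substitutes the
# Herrero CRFF table, and FeedParams.crff_provenance records that.
# Representative magnitudes; editable for real-data runs.
fcr:
  - {animal: cattle, product: meat, value: 330}
  - {animal: cattle, product: meat, system: grazing, value: 490}
  - {animal: cattle, product: meat, system: mixed, value: 280}
  - {animal: cattle, product: meat, system: intensive, value: 180}
  - {animal: cattle, product: milk, value: 85}
  - {animal: cattle, product: milk, system: intensive, value: 50}
  - {animal: sheep_goat, product: meat, value: 400}
  - {animal: sheep_goat, product: milk, value: 105}
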