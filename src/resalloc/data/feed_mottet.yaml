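# Mottet-style feed conversion table: two world regions (OECD / non-OECD),
# split by production system (grazing, mixed, feedlot -> canonical
# "intensive").  Representative magnitudes; editable for real-data runs.
fcr:
  - {animal: cattle, product: meat, value: 380}
  - {animal: cattle, product: milk, value: 95}
  - {animal: sheep_goat, product: meat, value: 440}
  - {animal: sheep_goat, product: milk, value: 115}
  - {region: oecd, animal: cattle, product: meat, value: 260}
  - {region: oecd, animal: cattle, product: meat, system: intensive, value: 170}
  - {region: oecd, animal: cattle, product: milk, value: 70}
  - {region: non_oecd, animal: cattle, product: meat, value: 470}
  - {region: non_oecd, animal: cattle, product: meat, system: grazing, value: 560}
  - {region: non_oecd, animal: cattle, product: milk, value: 120}
crff:
  - {animal: cattle, product: meat, value: 0.22}
  - {animal: cattle, product: milk, value: 0.22}
  - {animal: sheep_goat, product: meat, value: 0.18}
  - {animal: sheep_goat, product: milk, value: 0.18}
  - {region: oecd, animal: cattle, product: meat, value: 0.07}
  - {region: oecd, animal: cattle, product: milk, value: 0.07}
  - {region: non_oecd, animal: cattle, product: meat, value: 0.38}
  - {region: non_oecd, animal: cattle, product: meat, system: mixed, value: 0.45}
  - {region: non_oecd, animal: cattle, product: milk, value: 0.35}
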