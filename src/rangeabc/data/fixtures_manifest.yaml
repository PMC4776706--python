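strip-16:
  file: strip16.yaml
  n_rows: 1
  n_cols: 16
  counts:
    land: 16
    barrier: 0
    corridor: 0
    refuge: 0
  n_samples: 8
  groups:
    AFR: 2
    ENA: 2
    CAS: 2
    EAS: 2
  origin:
  - 0
  - 0
  note: synthetic schematic fixture; geometry is qualitative, not geographic
island-pair:
  file: island_pair.yaml
  n_rows: 1
  n_cols: 2
  counts:
    land: 2
    barrier: 0
    corridor: 0
    refuge: 0
  n_samples: 2
  groups:
    AFR: 1
    ENA: 1
    CAS: 0
    EAS: 0
  origin:
  - 0
  - 0
  note: synthetic schematic fixture; geometry is qualitative, not geographic
schematic-old-world-small:
  file: schematic_old_world_small.yaml
  n_rows: 30
  n_cols: 60
  counts:
    land: 939
    barrier: 82
    corridor: 4
    refuge: 261
  n_samples: 22
  groups:
    AFR: 6
    ENA: 7
    CAS: 4
    EAS: 5
  origin:
  - 17
  - 30
  note: synthetic schematic fixture; geometry is qualitative, not geographic
schematic-old-world-mini:
  file: schematic_old_world_mini.yaml
  n_rows: 12
  n_cols: 24
  counts:
    land: 146
    barrier: 11
    corridor: 2
    refuge: 43
  n_samples: 8
  groups:
    AFR: 2
    ENA: 2
    CAS: 2
    EAS: 2
  origin:
  - 9
  - 10
  note: synthetic schematic fixture; geometry is qualitative, not geographic
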