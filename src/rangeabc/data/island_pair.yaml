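deme_side_km: 150
origin:
- 0
- 0
grid: 'LL

  '
samples:
- label: IslA
  row: 0
  col: 0
  n: 10
  group: AFR
- label: IslB
  row: 0
  col: 1
  n: 10
  group: ENA
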