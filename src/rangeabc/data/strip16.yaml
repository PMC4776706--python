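deme_side_km: 150
origin:
- 0
- 0
grid: 'LLLLLLLLLLLLLLLL

  '
samples:
- label: S0
  row: 0
  col: 0
  n: 5
  group: AFR
- label: S1
  row: 0
  col: 2
  n: 5
  group: AFR
- label: S2
  row: 0
  col: 5
  n: 5
  group: ENA
- label: S3
  row: 0
  col: 7
  n: 5
  group: ENA
- label: S4
  row: 0
  col: 9
  n: 5
  group: CAS
- label: S5
  row: 0
  col: 11
  n: 5
  group: CAS
- label: S6
  row: 0
  col: 13
  n: 5
  group: EAS
- label: S7
  row: 0
  col: 15
  n: 5
  group: EAS
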