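deme_side_km: 150
origin:
- 9
- 10
grid: '........................

  ......LLLLLLLLLLLLLLLLLL

  ......LLLLLLLLLBBBLLLLLL

  ......LRRRRLLLLLLLLRRRRL

  ......LRRRRLLLLLLLLRRRRL

  ...........CC...........

  .LRRRRRRLLLLL...........

  .BBBBBBBBLLLL...........

  .LLLLLLLLLLLL...........

  .LRRRRRRRLLLL...........

  .LRRRRRRRLLLL...........

  .LRRRRRRRLLLL...........

  '
samples:
- label: Afr1
  row: 9
  col: 4
  n: 8
  group: AFR
- label: Afr2
  row: 11
  col: 7
  n: 8
  group: AFR
- label: Eur1
  row: 2
  col: 8
  n: 8
  group: ENA
- label: NAfr1
  row: 6
  col: 4
  n: 8
  group: ENA
- label: CAs1
  row: 1
  col: 12
  n: 8
  group: CAS
- label: CAs2
  row: 1
  col: 16
  n: 8
  group: CAS
- label: EAs1
  row: 2
  col: 21
  n: 8
  group: EAS
- label: EAs2
  row: 4
  col: 21
  n: 8
  group: EAS
crossings:
- - - 6
    - 2
  - - 4
    - 6
- - - 7
    - 12
  - - 4
    - 14
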