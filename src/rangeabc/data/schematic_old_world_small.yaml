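deme_side_km: 150
origin:
- 17
- 30
grid: '............................................................

  ..................LLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLL.

  ..................LLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLL.

  ..................LLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLLL.

  ..................LLLLLLLLLLLLLLLLLLLLLLLLBBBBBBLLLLLLLLLLL.

  ..................LLLLLLLLLLLLLLLLLLLLLLLLBBBBBBLLLLLLLLLLL.

  ............LLLLLLLLLLLLLLLLLLLLLLLLLLLLLLBBBBBBLLLLLLLLLLL.

  ............LLRRRRRRRRRRRRRRRRRRRLLLLLLLLLLLLLLLLLLLLLLLLLL.

  ............LLRRRRRRRRRRRRRRRRRRRLLLLLLLLLLLLLLLLLRRRRRRLLL.

  .................................LLLLLLLLLLLLLLLLLRRRRRRLLL.

  ....LRRRRRRRRRRRRRRRLLLLLLLLLLCCCCBBBBBBLLLLLLLL..RRRRRL....

  ....BBBBBBBBBBBBBBBBBBBBBBBBBBLLLLBBBBBBLRRRRRRL..RRRRRL....

  ....BBBBBBBBBBBBBBBBBBBBBBBBBBLLLL.LLLLLLRRRRRRL..LLLLLL....

  ....LLLLLLLLLLLLLLLLLLLLLLLLLLLLLL......LRRRRRRL............

  ....LLLLLLLLLLLLLLLLLLLLLLLLLLLLLL..........................

  ....LLLLLLLLLLLLLLLLLLLLLLLLLLLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLRRRRRRRRRRRRRRRRRRRRRRRRLLLL..........................

  ....LLLLLLLLLLLLLLLLLLLLLLLLLLLLLL..........................

  ..........LLLLLLLLLLLLLLLL..................................

  ..........LLLLLLLLLLLLLLLL..................................

  ..........LLLLLLLLLLLLLLLL..................................

  ..........LLLLLLLLLLLLLLLL..................................

  ..........LLLLLLLLLLLLLLLL..................................

  ............................................................

  '
samples:
- label: Bantu
  row: 15
  col: 8
  n: 15
  group: AFR
- label: Mandenka
  row: 15
  col: 20
  n: 15
  group: AFR
- label: Yoruba
  row: 18
  col: 12
  n: 15
  group: AFR
- label: Biaka
  row: 21
  col: 24
  n: 15
  group: AFR
- label: San
  row: 25
  col: 14
  n: 15
  group: AFR
- label: Zulu
  row: 27
  col: 20
  n: 15
  group: AFR
- label: Orcadian
  row: 2
  col: 20
  n: 15
  group: ENA
- label: Russian
  row: 3
  col: 28
  n: 15
  group: ENA
- label: Basque
  row: 6
  col: 15
  n: 15
  group: ENA
- label: Tuscan
  row: 7
  col: 24
  n: 15
  group: ENA
- label: Adygei
  row: 5
  col: 32
  n: 15
  group: ENA
- label: Mozabite
  row: 10
  col: 10
  n: 15
  group: ENA
- label: Druze
  row: 8
  col: 34
  n: 15
  group: ENA
- label: Mongola
  row: 2
  col: 38
  n: 10
  group: CAS
- label: Uygur
  row: 3
  col: 44
  n: 10
  group: CAS
- label: Pathan
  row: 7
  col: 38
  n: 15
  group: CAS
- label: Sindhi
  row: 8
  col: 41
  n: 15
  group: CAS
- label: Yakut
  row: 2
  col: 52
  n: 15
  group: EAS
- label: Japanese
  row: 5
  col: 54
  n: 15
  group: EAS
- label: Han
  row: 8
  col: 52
  n: 15
  group: EAS
- label: Dai
  row: 11
  col: 52
  n: 15
  group: EAS
- label: Cambodian
  row: 12
  col: 54
  n: 15
  group: EAS
crossings:
- - - 10
    - 13
  - - 8
    - 13
- - - 13
    - 33
  - - 12
    - 35
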