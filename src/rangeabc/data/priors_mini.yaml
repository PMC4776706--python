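# Desk-scale conditions for the 12x24 mini fixture.  The time axis is
# compressed and per-step drift strengthened relative to the study-scale
# priors: on a map ~5x smaller, serial founder effects accumulate over
# far fewer colonisation steps, so preserving the study's
# diversity-gradient regime requires fewer founders per step (smaller K,
# lower m).  Rate-like parameters keep their study supports.  One
# simulation runs in a fraction of a second.
parameters:
  T_STARTEXP: {dist: uniform, lower: 350, upper: 550}
  T_OOA: {dist: uniform, lower: 180, upper: 280}
  Ne_ANC: {dist: uniform, lower: 1000, upper: 4000}
  K: {dist: uniform, lower: 15, upper: 120}
  r: {dist: uniform, lower: 0.2, upper: 1.0}
  m: {dist: uniform, lower: 0.03, upper: 0.12}
  LDD_PROP: {dist: uniform, lower: 0.0, upper: 0.05}
  mu_bar: {dist: uniform, lower: 2.0, upper: 6.0}
  alpha: {dist: uniform, lower: 0.5, upper: 2.0}
  STR_MUTRATE: {dist: uniform, lower: 5.0e-5, upper: 3.0e-4}
  KNeo: {dist: uniform, lower: 300, upper: 1000}
constants:
  T_SCONTR: 160
  n_contraction_events: 30
  contraction_gap: 2        # 30 x 2 = 60 generations of contraction
  refuge_duration: 40
  t_neolithic: 50
  ldd_cap: 6
  deme_side_km: 150
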