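# Study-scale prior supports.  Printed priors: STR_MUTRATE, KNeo,
# T_STARTEXP, T_OOA.  The remaining supports are RECONSTRUCTED as the
# smallest round intervals containing the reported 95% posterior HPDIs.
# Times in generations BP (25 years/generation), sizes in diploids.
parameters:
  T_STARTEXP: {dist: uniform, lower: 3200, upper: 6000}
  T_OOA: {dist: uniform, lower: 1200, upper: 3000}
  Ne_ANC: {dist: uniform, lower: 5000, upper: 20000}
  K: {dist: uniform, lower: 50, upper: 2000}
  r: {dist: uniform, lower: 0.2, upper: 1.0}
  m: {dist: uniform, lower: 0.05, upper: 0.3}
  LDD_PROP: {dist: uniform, lower: 0.0, upper: 0.05}
  mu_bar: {dist: uniform, lower: 2.0, upper: 6.0}
  alpha: {dist: uniform, lower: 0.5, upper: 2.0}
  STR_MUTRATE: {dist: uniform, lower: 5.0e-5, upper: 3.0e-4}
  KNeo: {dist: uniform, lower: 2500, upper: 7500}
constants:
  T_SCONTR: 1000            # contraction onset, generations BP
  n_contraction_events: 30
  contraction_gap: 4        # generations between events (30 x 4 = 120)
  refuge_duration: 160      # generations confined to refugia
  t_neolithic: 320          # generations BP of the Neolithic K increase
  ldd_cap: 6                # maximum LDD distance, demes
  deme_side_km: 150
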