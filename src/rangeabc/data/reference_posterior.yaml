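# Reported posterior summaries of the demographic parameters under the
# best-fitting model (occupied-places LDD with a glacial range
# contraction), used by worked examples and derived-quantity reports.
# Times in years (25-year generations), sizes in diploid individuals.
model: LDDRCop
parameters:
  T_STARTEXP_years: {mode: 80704, mean: 94903, median: 91777}
  T_OOA_years: {mode: 73568, mean: 65924, median: 67477}
  Ne_ANC: {mode: 10327, mean: 11795, median: 11386}
  K: {mode: 826, mean: 1036, median: 992}
  LDD_PROP: {mode: 0.044, mean: 0.038, median: 0.040}
  r: {mode: 0.429, mean: 0.561, median: 0.545}
  mu_bar_demes: {mode: 5.357, mean: 4.780, median: 4.946}
  alpha: {mode: 1.209, mean: 1.251, median: 1.249}
  m: {mode: 0.110, mean: 0.155, median: 0.148}
  Nm: {mode: 39, mean: 37}
  LDD_Nm: {mode: 8, mean: 8, median: 8}
  STR_MUTRATE: {mode: 1.74e-4, mean: 1.72e-4, median: 1.72e-4}
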