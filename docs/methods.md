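# Methods

`rangeabc` couples a forward-in-time lattice demography with a backward
structured coalescent and an approximate Bayesian computation (ABC) layer.
This note records the model, its assumptions, the numerical choices, and
what the packaged synthetic worlds do and do not show about real data.

## Demographic model

The world is a rectangular grid of square demes (default side 150 km,
22,500 km²; 250 km is supported as a sensitivity setting).  Each deme
carries a haploid gene count `N_t` regulated logistically,

    N_{t+1} = N_t + r·N_t·(1 − N_t/K_t),

with intrinsic growth rate `r` and carrying capacity `K_t` (diploid `K`
doubled internally to gene copies).  A deme whose capacity drops to zero
dies; a deme seeded above capacity (the origin holds `2·Ne_ANC` genes at
the expansion onset `T_STARTEXP`) declines to `K` rather than
overshooting negative — the discrete logistic is otherwise unstable for
`N ≫ K`.  Growth is deterministic; migration is stochastic — integer gene
counts drawn per generation — so drift enters through migration sampling
and, chiefly, through the coalescent resampling of the genetic layer.

Each generation, every occupied deme emits `M = round(2·N_t·m)` migrant
genes.  `Binomial(M, LDD_PROP)` of them are long-distance dispersers
(LDD); the rest are split by an equal-probability multinomial over the
four von Neumann neighbours.  Genes aimed at sea, barriers, or currently
uninhabitable demes are lost; we deliberately do not renormalise over
land neighbours, so emigration pressure is independent of coastline
shape.  An LDD gene travels `x ~ Gamma(shape α, rate α/μ̄)` demes,
rounded to the nearest integer and resampled until it lies in [2, 6]
(LDD is non-adjacent by definition and capped at 6 demes = 900 km), in a
uniform random direction, the landing point rounded to the lattice.
Three LDD regimes restrict target validity: `any`, `empty_only` (ep:
every event is a founding event), `occupied_only` (op: gene flow between
colonised demes only).  Invalid targets are discarded (the gene dies)
and counted in diagnostics, so the regimes differ only through target
validity.

Habitability changes at fixed epochs: corridor demes (the Levant)
open at the out-of-Africa time `T_OOA`; under range contraction (RC) the
glacial maximum is modelled by 30 contraction events starting 1,000
generations BP, 4 generations apart (120 generations total), each
removing latitudinal rows of habitable demes from the north toward the
refugia (the exact per-event row assignment is not constrained by the
epoch totals; we split the removable rows into 30 near-equal north-to-
south chunks).  After the last event only the refugia remain habitable
for 160 generations, then the full range reopens.  Under the Neolithic
variant, capacity switches from `K` to `KNeo` 320 generations BP.  The
named scenarios (noLDDnoRC, noLDDRC, LDDnoRC, LDDRC, the ep/op variants,
and the Neolithic noLDDRC extension) map 1:1 onto the flag combinations.

Everything the genetic layer needs is recorded per generation: deme
densities and immigrant counts by source deme, split into adjacent and
LDD entries.

## Coalescent and mutation

Sampled genes are traced backward through the record.  A lineage in deme
d moves to source s with probability `immigrants(s→d)/N(d)` and stays
with the residual mass.  Co-resident lineages (k of them in a deme of
haploid size N) coalesce with probability `min(1, k(k−1)/(2N))`, at most
one merger per deme per generation — an approximation that is accurate
while `k ≪ N`, which holds at the deme sizes used (k per deme per locus
is at most the local sample size, tens, against deme sizes of hundreds
to thousands of genes).  Lineages alive at `T_STARTEXP` enter the
ancestral origin deme of `2·Ne_ANC` genes and coalesce under the
continuous-time Kingman approximation (exponential waiting times at rate
k(k−1)/2 / (2·Ne_ANC)) — exact in distribution at these sizes and
removes an unbounded generation loop.

Microsatellites follow the strict stepwise mutation model:
`Poisson(rate × branch length)` mutations per branch, each ±1 repeat
with probability ½.  The root repeat count is fixed at 30 for all loci;
every statistic used is translation invariant, so the anchor is
arbitrary.  The floor at one repeat is implemented as a single final
reflection (`v → 2−v` when `v < 1`); with root 30 and the mutation rates
in the priors the boundary is effectively never reached.

## Summary statistics (39)

Per population and locus: allele count K, unbiased expected
heterozygosity `H = n/(n−1)·(1 − Σp²)`, and the modified
Garza–Williamson statistic `NGW = K/(range+1)` with the range in repeat
units.  Locus means and locus SDs are averaged over populations within
four regional groups (AFR, ENA, CAS, EAS): 24 values.  SDs over loci of
the three statistics on the pooled all-individual sample: 3 values.
Differentiation uses R_ST — a two-level AMOVA variance decomposition of
repeat counts — with per-locus numerator and denominator components
summed over loci before dividing; negative per-locus among-population
components are truncated at zero (the usual convention for
variance-component estimators, and it makes R_ST of identical
populations exactly 0).  Pairwise R_ST is averaged within each group (4)
and between each group pair (6).  Finally, per-population mean H is
regressed on least-cost distance from the expansion origin under two
routings — land through the Levant only (`slope_levant`), and with the
Gibraltar and Horn-of-Africa sea crossings enabled (`slope`): 2 values.
The 39 names are stable and are the join keys of the ABC layer; the
exact composition of the set is reconstructed from the counts above (a
corrected list can be dropped in because the layer is name-driven).
Least-cost paths run over 4-neighbour land edges of one deme side each;
crossing edges cost the Euclidean lattice distance times the deme side.

## ABC

Model choice: summaries standardized by reference-table column means/SDs
(the conventional choice; the standardization basis is a config switch),
Euclidean rejection retaining exactly `⌈tolerance·n⌉` rows (ties by row
order), then a distance-weighted multinomial logistic regression of the
model label on the summaries, evaluated at the observed vector.  Weights
are Epanechnikov in the retained distances.  The regression carries an
L2 penalty scaled to the retained count (`C = 3/n` in scikit-learn
terms); this keeps the fit defined under complete separation and returns
near-uniform probabilities when summaries carry no model information,
while leaving discrimination intact (in strongly separated problems the
rejection step itself concentrates the retained set on one model).  The
penalty scale is exposed as a parameter (`c_scale`): the default (3) is
the calibration-safe setting; the packaged desk-scale power studies use
`c_scale = 300`, because with retained sets of only ~100 rows the
calibration-strength penalty never lifts any model's probability above
the 0.5 assignment threshold and every pseudo-observed dataset would be
counted unassigned.  Uncertainty from the choice of
loci: the observed vector is recomputed over bootstrap resamples of loci
(without replacement within a replicate) and per-model probabilities are
reported as order-statistic medians with central 95% intervals.

Parameter estimation: each summary column is Box-Cox transformed
(columns that can be ≤ 0 are shifted by `−min + ε` first; λ fitted by
maximum likelihood within [−2, 2]), standardized, and projected onto
partial-least-squares components fitted against the parameters (default
12 components; an RMSE-versus-components curve is emitted to justify the
choice).  Rejection runs in component space; retained parameters get a
weighted local-linear regression adjustment on the components, and
adjusted draws are truncated to the prior support (the truncated
fraction is reported).  Two guards keep the adjustment honest at small
retained counts: the regression uses at most `n_retained/5` leading
components, and residuals are cross-fitted (out-of-fold, 5 folds) —
in-sample residuals are variance-deflated by the hat matrix, which makes
the adjusted posterior artificially narrow and the HPDIs undercover.
Point summaries: weighted mean and median, kernel-density mode (Gaussian
KDE, Silverman bandwidth, 512-point grid), and the shortest interval
holding 95% of the weighted sample (HPDI).

Power studies draw pseudo-observed data sets (PODS) from the reference
simulations, score each against the table with its own row removed
(leave-one-out), and assign a PODS to a model when its posterior
probability exceeds a threshold (0.50 or 0.85), else count it
unassigned.

Goodness of fit: 2D highest-density-region tail probabilities against
the bootstrap cloud of observed vectors (p = fraction of cloud points
whose KDE density falls below the density at the queried point), and
posterior predictive checks in PCA space (first four components, six
pair plots, 50/75/95% HDR envelopes, observed point's HDR p-value).

## Priors

Printed supports: `STR_MUTRATE ~ U[5×10⁻⁵, 3×10⁻⁴]`,
`KNeo ~ U[2500, 7500]`, `T_STARTEXP ~ U[3200, 6000]` generations,
`T_OOA ~ U[1200, 3000]` generations.  The remaining supports are
reconstructed as the smallest round intervals containing the reported
95% posterior HPDIs: `K ~ U[50, 2000]`, `m ~ U[0.05, 0.3]`,
`LDD_PROP ~ U[0, 0.05]`, `r ~ U[0.2, 1.0]`, `μ̄ ~ U[2, 6]`,
`α ~ U[0.5, 2]`, `Ne_ANC ~ U[5000, 20000]`.  All live in one editable
priors file (`data/priors.yaml`, labelled reconstructed).  Epoch
constants (contraction onset/duration, refuge duration, Neolithic time,
LDD cap, generation time 25 y) are fixed, not estimated.

## Synthetic worlds and desk-scale conditions

The real Old-World map is replaced by packaged schematic ASCII fixtures:
`schematic-old-world-small` (30×60; Africa–Eurasia topology with a
Levant corridor, Sahara, Arabian and Himalayan barrier bands, four
refuge blocks, Gibraltar and Horn-of-Africa crossings, and 22 sampled
populations in 4 groups, two of them with n = 10 and the rest n = 15,
emulating the shape of the real panel) and `schematic-old-world-mini`
(12×24, 8 populations of 8 diploids — the workhorse for simulation-heavy
studies), plus `strip-16` and `island-pair` for analytic checks.  The
fixtures are generated once from rectangle specifications, validated
(mask invariants, corridor gating, reachability of every sample), and
shipped with a manifest of cell counts.

Simulation-heavy validations (model-choice power, parameter recovery)
run on the mini fixture under `data/priors_mini.yaml`.  Two things are
rescaled relative to the study conditions, both consequences of the
smaller map.  The time axis is compressed (expansion 350–550
generations, out-of-Africa 180–280, contraction onset 160 with
2-generation gaps, 40-generation refuge phase) so one simulation takes
a fraction of a second.  And per-step genetic drift is strengthened
(`K ~ U[15, 120]`, `m ~ U[0.03, 0.12]`): serial founder effects
accumulate over ~25 colonisation steps on the mini map instead of ~60,
and with study-scale deme sizes (hundreds of founders per step) the
diversity gradient — the signal the whole analysis rests on — simply
does not form; fewer founders per step restores the regime.  Rate-like
parameters (`r`, `LDD_PROP`, `μ̄`, `α`, `STR_MUTRATE`) keep their study
supports.  Simulated datasets carry 24–40 loci depending on the study.
These sizes are the package's desk-scale study conditions; the
acceptance script reports the problem size it used with each number.

What the synthetic worlds do not emulate: real coastline geometry and
least-cost distances, paleo-vegetation refuge polygons, sea-level
change, ascertainment of the real microsatellite panel (trinucleotide
selection), archaic admixture, and any environmental heterogeneity in
`K`, `r` or `m`.  Passing the packaged validations therefore shows that
the machinery (simulator, statistics, inference) behaves correctly and
that the qualitative genetic signatures of LDD and RC are as expected —
not that the schematic worlds reproduce the empirical posterior
probabilities, which depend on the real map, the real panel and
simulation farms orders of magnitude larger.

## Failed replicates and degenerate inputs

A forward replicate is rejected (and redrawn, with a count) when the
metapopulation goes extinct or when a sampled deme holds fewer genes at
present than the design samples from it — slow-spread parameter corners
cannot cover the most distant samples.  Zero-variance summary columns
are dropped from rejection distances with a warning; monomorphic loci
across both populations give R_ST = 0 by convention; a KDE over a
degenerate (fully truncated) posterior falls back to the weighted
median for the mode.

## Known limitations

- One merger per deme per generation in the coalescent; biased only when
  local sample sizes approach deme sizes.
- Migrant counts are rounded (`round(2Nm)`), so demes below
  `1/(4m)` genes emit no migrants; invisible at the priors used.
- The regression-adjusted ABC posterior can undercover for parameters
  the summaries barely constrain (e.g. `Ne_ANC` under weak drift);
  coverage is validated pooled over parameters.
- The MLR penalty trades a little confidence in separable problems for
  calibration in uninformative ones; both regimes are tested.
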