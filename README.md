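# rangeabc

Spatially explicit simulation and likelihood-free inference for the
settlement of the Old World by modern humans — and, more generally, for
range expansions with long-distance dispersal (LDD) over heterogeneous
landscapes.

## The problem

Human microsatellite diversity declines roughly linearly with distance
from Africa, yet non-African populations keep higher heterozygosity and
lower differentiation than a pure stepping-stone expansion predicts.
Two processes could explain the discrepancy: long-distance dispersal
(migrants jumping several demes per generation, reshuffling diversity
behind the colonisation front) and a glacial range contraction (RC,
populations squeezed into southern refugia during the last glacial
maximum and re-expanding afterwards).  `rangeabc` implements the
machinery to ask which combination of these processes a
population-structured microsatellite panel supports:

1. **Forward lattice demography.**  Square demes with logistic
   regulation `N_{t+1} = N_t + rN_t(1 − N_t/K)`, nearest-neighbour
   migration of `2N_t m` gene copies, and LDD: `Binomial(2N_t m,
   LDD_PROP)` migrants travelling `x ~ Gamma(α, α/μ̄)` demes (rounded,
   truncated to 2–6 demes) in a uniform direction.  Regimes restrict
   LDD to empty demes only (*ep*, pure founding events) or occupied
   demes only (*op*, pure gene flow).  Habitability follows fixed
   epochs: a Levant corridor opens at `T_OOA`; under RC, 30 contraction
   events (starting 1,000 generations BP, 120 generations total)
   remove rows of demes down to four refuge blocks held for 160
   generations.
2. **Backward structured coalescent.**  Lineages of the sampled genes
   retrace the recorded immigration fields; co-resident lineages
   coalesce at rate `k(k−1)/(2N)`; surviving lineages coalesce in the
   ancestral deme (`2·Ne_ANC` genes).  Microsatellites mutate under the
   strict stepwise model.
3. **39 summary statistics.**  Allele number K, unbiased heterozygosity
   H and the modified Garza–Williamson statistic NGW (means and SDs,
   averaged within four regional groups AFR/ENA/CAS/EAS, plus pooled
   SDs), R_ST-based F_ST within and between groups (AMOVA variance
   decomposition of repeat counts), and the slope of H against
   least-cost distance from the origin under two routings.
4. **ABC.**  Rejection sampling, multinomial-logistic-regression model
   choice with locus-bootstrap confidence intervals, Box-Cox + PLS +
   regression-adjusted parameter posteriors with 95% HPDIs, PODS power
   studies, and 2D HDR / posterior-predictive-PCA goodness-of-fit.

No external data are required: packaged schematic Old-World fixtures
(ASCII grids with corridor, barriers, refugia, sea crossings, and a
22-population sampling design emulating the shape of the real panel)
and prior files reproduce every input programmatically.  See
`docs/methods.md` for the model details and the desk-scale study
conditions.

## Worked example

Simulate one scenario on the mini world, summarize it, and ask the
model-choice machinery which scenario produced it:

```python
import dataclasses
from rangeabc import PriorSpec, load_fixture, sample_prior, make_pseudo_observed, summarize
from rangeabc.pipeline import build_reference_table
from rangeabc.abc import model_choice

world = load_fixture("schematic-old-world-mini")
priors = PriorSpec.load("priors_mini")

# a pseudo-observed panel generated under occupied-places LDD + contraction
params = sample_prior(priors, "LDDRCop", seed=7)
params = dataclasses.replace(params, LDD_PROP=0.04, mu_bar=4.8, alpha=1.25)
panel = make_pseudo_observed(priors.scenario("LDDRCop"), params, world,
                             n_loci=24, seed=7, schedule=priors.schedule())
obs = summarize(panel, landscape=world)
print(obs[["H_AFR", "H_EAS", "FST_AFR-EAS", "slope"]].round(4))

# a small reference table over two competing scenarios
table, _ = build_reference_table(world, ["noLDDnoRC", "LDDRCop"], priors,
                                 n_sims=60, n_loci=8, seed=1)
res = model_choice(table, obs, tolerance=0.2, c_scale=300)
print(res.probabilities.round(4))
```

Output (seeds as above):

```
H_AFR          0.4420
H_EAS          0.1882
FST_AFR-EAS    0.4087
slope         -0.0002
dtype: float64
   LDDRCop  noLDDnoRC
0   0.9918     0.0082
```

African heterozygosity exceeds East Asian heterozygosity (serial
founder effects), the H-versus-distance slope is negative, and the
model-choice layer confidently recovers the generating scenario.

The same pipeline runs from the shell: `rangeabc build-landscape`,
`simulate-forward`, `simulate-genetics`, `sumstats`, `abc-sample`,
`model-choice`, `estimate`, `power`, `ppc`, `make-pods` (all accept
`--seed` and `--out`).

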