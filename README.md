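# sbhbm — social brain morphology with hierarchical Bayesian regression

`sbhbm` is a tested, reusable pipeline for population analyses of
social-brain morphology. It answers questions of the form: *within each
sex × social-trait stratum of a large cohort, how does gray-matter volume in
each of the 36 regions of the social brain co-vary with age?* — using
spherical ROI volumetry on MNI-space maps and a group-stratified hierarchical
Bayesian regression with network-nested priors, summarized by posterior means
and 95% highest-posterior-density intervals (HPDIs).

It is aimed at researchers working with large population-imaging phenotypes
(UK-Biobank-scale structural MRI plus questionnaire items) who want
uncertainty-aware, partially pooled estimates instead of mass-univariate
tests, and a fully synthetic test bed so every stage runs without restricted
data.

## The model

For participant *i* with z-scored region volumes `x_i1..x_i36`, z-scored
confounds `c_i` (body mass, head-size scaling), z-scored age `y_i` and group
`g_i ∈ {male/low, male/high, female/low, female/high}` on one social index
(support, household, friendship):

```
y_i     ~ Normal( Σ_j x_ij β_j[g_i] + Σ_k c_ik γ_k ,  σ )
β_j[g]  ~ Normal( β_net(j)[g] , τ_net(j)[g] )     36 regions, 4 groups
β_m[g]  ~ Normal( 0 , λ_g )                        4 networks
τ, λ, σ ~ Half-Cauchy(0, 1),   γ_k ~ Normal(0, 1)
```

Region coefficients borrow strength within their network (visual-sensory,
limbic, intermediate, higher-associative); groups are formed by median
splitting the social item (household: lives alone vs with others). Inference
is by a seed-deterministic blocked Gibbs sampler (conjugate Gaussian updates
for coefficients, slice sampling for scales); see `docs/methods.md`.

## Worked example

```python
from sbhbm import (SamplerConfig, SimulationConfig, build_design,
                   generate_cohort, load_atlas, sample_posterior,
                   summarize_posterior)

atlas = load_atlas("default")
cohort = generate_cohort(SimulationConfig(n=1500, seed=7), atlas)
design = build_design(cohort.volumes, cohort.phenotypes, "household", atlas=atlas)
draws = sample_posterior(design, sampler=SamplerConfig(n_draws=1500, burn_in=500,
                                                       chains=2, seed=7))
summary = summarize_posterior(draws, atlas)
```

Running `python examples/02_fit_hierarchical_model.py` (the same steps)
prints:

```
design: n=1490, group sizes=[238, 484, 260, 508]

strongest region x group associations with z-scored age:
  HC_L       female/lives with others   mean=-0.241 95% HPDI=(-0.282, -0.195)
  AI_R       female/lives with others   mean=-0.205 95% HPDI=(-0.248, -0.164)
  TP_R       male/lives with others     mean=-0.194 95% HPDI=(-0.234, -0.152)
  TP_L       female/lives with others   mean=+0.189 95% HPDI=(+0.150, +0.231)
  IFG_L      female/lives alone         mean=-0.184 95% HPDI=(-0.244, -0.131)

convergence: max split R-hat = 1.050 (should be ~1), min ESS = 54
```

Each line is one region coefficient in one stratum: the posterior mean change
in z-scored age per SD of regional volume, with the shortest interval holding
95% posterior mass. An HPDI excluding zero flags a credible volume–age
association for that group. (This cohort is synthetic; the coefficients
reflect its known generating truth, which is how the pipeline is validated —
see `examples/03_recovery_experiment.py`, which reports
`correlation(truth, posterior means) = 0.984` and `coverage = 0.917` at
n = 2000.)

The command-line interface mirrors the stages:

```bash
sbhbm simulate --out cohort/ --seed 7
sbhbm extract  --images maps/ --atlas default --diameter-mm 5 --fwhm-mm 5 --out volumes.csv
sbhbm prepare  --phenotypes cohort/phenotypes.csv --volumes cohort/volumes.csv \
               --index household --out design.npz
sbhbm fit      --design design.npz --draws 5000 --burn-in 4000 --chains 2 --seed 7 --out fit/
sbhbm report   --summary fit/summary_household.csv --network limbic --out limbic.png
sbhbm run      --out full_run/ --seed 7          # all stages, all three indices
```

Real analyses start from preprocessed, MNI152-registered, head-size-corrected
GM maps (NIfTI) or a precomputed participant × region CSV; the packaged atlas
ships synthetic placeholder coordinates, so supply a coordinate CSV
(`region_id,name,hemisphere,network,x,y,z`) for real extractions.

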