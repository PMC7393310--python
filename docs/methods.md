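# Methods

## Problem and model

The package implements a population analysis of social-brain morphology: for
each of 36 meta-analytically defined regions of the "social brain" (grouped
into visual-sensory, limbic, intermediate and higher-associative networks),
how strongly does regional gray-matter volume co-vary with age within each of
four population strata (sex crossed with a dichotomized social trait —
social-support frequency, household situation, or friendship satisfaction)?

With `x_j` the z-scored mean GM volume of region `j`, `c_k` z-scored
confounds (body mass, head-size scaling), `y` z-scored age and `g ∈ {0..3}`
the participant's group,

```
y_i        ~ Normal( Σ_j x_ij · β_j[g_i]  +  Σ_k c_ik · γ_k ,  σ )
β_j[g]     ~ Normal( β_net(j)[g], τ_net(j)[g] )        region level
β_m[g]     ~ Normal( 0, λ_g )                          network level
τ_m[g], λ_g, σ ~ Half-Cauchy(0, 1)
γ_k        ~ Normal(0, 1)
```

Region coefficients are partially pooled toward their network coefficient:
networks with coherent age associations pull their member regions together,
while the Half-Cauchy spreads let a genuinely divergent region escape.
Confound coefficients carry no group subscript (one `γ` per confound for the
whole cohort), and the noise scale is shared across groups. One independent
model is fit per social index; coefficients are reported as associations
between z-scored volume and z-scored age, with no causal or directional
claim.

Structural choices the model display leaves open, and what this package
does:

* **Region-level spread.** One spread per (network, group),
  `τ_m[g] ~ Half-Cauchy(0,1)` — the minimal structure in which network-level
  information regularizes region coefficients with per-group strength.
* **Network-coefficient scale.** `λ_g` is shared across the four networks
  within a group (default); `PriorConfig(network_scale_shared=False)` selects
  one scale per (network, group) instead.
* **Parameter state.** The scale `λ` of the network-coefficient prior is an
  explicit latent (centered parameterization); the implied joint density is
  unchanged relative to writing `β_m[g] ~ Normal(0, s), s ~ Half-Cauchy`.

## Inference

Posterior sampling is by **blocked Gibbs**:

* All coefficient blocks (region betas per group, confound betas, network
  betas) have conjugate Gaussian full conditionals and are sampled exactly
  via Cholesky-factor solves in canonical (precision/shift) form.
* The Half-Cauchy scale parameters (`τ`, `λ`, `σ`) have log-concave-ish
  non-conjugate conditionals and are updated by univariate slice sampling on
  the log scale (stepping-out + shrinkage, width 1, capped stepping).

Per-group Gram matrices (`XᵀX`, `Xᵀy`, `XᵀC`, `CᵀC`) are computed once, so a
sweep costs O(G·R³) for the coefficient blocks plus one O(n·R) residual pass
for the noise update. The sampler is deterministic given the seed: each chain
uses `default_rng(SeedSequence([seed, chain]))`. The default protocol is 2
chains so split R-hat is computable; `SamplerConfig(paper_protocol=True)`
reproduces the original single-chain 5000-draw / 4000-burn-in protocol.
With zero observations the same sweeps target the prior, which is how the
prior-recovery test works.

Degenerate switches (`hierarchy=False`, `fixed_noise_scale`,
`fixed_region_spread`) reduce the model to ridge regression with the
closed-form Gaussian posterior `N((XᵀX + I)⁻¹Xᵀy, ·)`; the test suite checks
the sampler against that analytic answer.

**Diagnostics.** Rank-normalized split R-hat and effective sample size per
scalar parameter via arviz; warnings above R-hat 1.05. Note that split R-hat
of two *identical* chains is close to, but not exactly, 1 (split halves of a
finite chain differ), so checks use a tolerance. Hierarchical scale
parameters mix the slowest; with 2×1000 kept draws, minimum ESS of order
50–100 on scale parameters is typical and adequate for posterior means and
95% HPDIs of the coefficients, which mix far faster.

**HPDI.** The 95% highest-posterior-density interval is the shortest
contiguous window of the sorted draws containing `ceil(0.95·S)` samples;
ties resolve to the smallest lower bound. This is exact for unimodal draws
and matches an exhaustive window search by construction (property-tested).

## ROI extraction

Gray-matter maps in MNI152 space are smoothed with a 5 mm FWHM Gaussian
(σ = FWHM/(2√(2 ln 2)) per axis, divided by the voxel size read from the
affine; zero-padded boundaries; kernel truncated at 6σ so interior mass error
is < 1e-8). Region means are then taken over spheres of 5 mm **diameter**
around each atlas coordinate; a voxel belongs to the sphere iff its center is
within 2.5 mm of the region center. Smoothing always precedes masking.
Spheres clipped by the grid are an error unless explicitly allowed; empty
spheres are always an error naming the region. Columns are z-scored with the
population convention (divide by n) — fixed so tests are exact; at cohort
sizes the n vs n−1 difference is immaterial.

The packaged atlas ships **synthetic coordinates** (plausible MNI locations
for the named regions, spaced ≥ 18.9 mm apart); the published meta-analytic
peaks are distributed separately and should be supplied as a CSV for real
analyses. All geometric tests use synthetic coordinates by design, so the
pipeline's correctness does not depend on the packaged coordinate values.

## Synthetic cohorts and ground truth

The generator emulates the study conditions: n = 10 129; 52.4% female;
age 40–70 (mean 55, SD 7.5); BMI 26.7 ± 4.3; head-size scaling 1 ± 0.1;
ordinal responses for the three social items with ~1–2% non-answer mass;
region volumes multivariate normal with within-network correlation 0.3 and
between-network 0.1. Response-category probabilities are invented (no source
prints them) and were chosen once so that, after median splitting, every
sex × trait group holds 15–35% of the cohort; they are fully configurable.

z-scored age is constructed from the model itself: true network coefficients
~ N(0, 0.2), region offsets ~ N(0, 0.1) per group, confound coefficients
~ N(0, 0.1), residual SD 0.8 — then the *entire generative equation* is
rescaled by one global factor (plus per-group factors equalizing signal
variance) so z-age has unit variance in every group. The rescaling preserves
every ratio of the scheme, including signal-to-noise (R² ≈ 0.9 — optimistic
for brain–age prediction but within the published range, and the regime in
which coefficient recovery is a sharp test); `GroundTruth` records the
effective (rescaled) coefficients, spreads and noise SD, which are exactly
what the fitted model should recover. Ages are mapped to years
(55 + 7.5·y) and truncated to [40, 70], clipping ~5% of records; the
distortion is second-order for recovery (attenuation and the re-z-scoring of
clipped ages nearly cancel).

What the generator does **not** emulate: realistic anatomy in fixture images
(regions are painted balls on a zero background), survey weighting,
socioeconomic covariates, item–item dependence, or volume–confound
correlation. Passing recovery tests therefore demonstrates the estimator's
correctness under the model, not robustness to real-data misspecification.

Fixture images paint each region's raw volume in an 18 mm-diameter ball at
the region coordinate. 18 mm is the smallest diameter, compatible with the
packaged atlas spacing, at which 5 mm FWHM smoothing erodes the mean over
the 5 mm extraction sphere by well under 1%: direct convolution of a ball
with the kernel gives mean erosion ≈ 1.9% at 15 mm, 0.7% at 16.5 mm and
0.23% at 18 mm, because a 15 mm ball leaves the sphere edge only ~2.4σ from
the ball boundary.

## Problem sizes and defaults used in checks

Parameter recovery runs at n = 2000 with 2 chains × 1500 draws (500
burn-in); the shrinkage comparison at n = 100 (where per-group least squares
is underdetermined and the minimum-norm solution is used); prior recovery at
2 × 2250 retained draws; pipeline determinism at n = 1000. These sizes were
chosen to make each property sharp at interactive cost; the full-scale
protocol (n = 10 129, 5000/4000 draws) runs unchanged via the same API.

## Known limitations

* The Gibbs sampler exploits the model's conditional conjugacy; changing the
  likelihood or priors to non-conjugate forms would require new updates
  (or a generic MCMC backend).
* Heavy-tailed hyperpriors mean prior-predictive summaries based on *means*
  are unstable by construction (a network coefficient's marginal prior is a
  normal/Half-Cauchy scale mixture with infinite variance); medians are the
  meaningful prior-location check.
* Median splitting discards within-group trait variation; this mirrors the
  analyzed design rather than a statistical recommendation.
* The extraction stage assumes preprocessed, MNI-registered, head-size
  normalized GM maps; no registration, segmentation or bias correction is
  performed.
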