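"""Fit the group-stratified hierarchical regression on a synthetic cohort.

Simulates 1500 participants, stratifies them by sex x household situation
(lives alone vs with others), and regresses z-scored age on the 36 z-scored
region volumes with partial pooling of region coefficients toward their
network. Prints the strongest region-level associations with their 95% HPDIs.
"""

from sbhbm import (
    PriorConfig,
    SamplerConfig,
    SimulationConfig,
    build_design,
    convergence_diagnostics,
    generate_cohort,
    load_atlas,
    sample_posterior,
    summarize_posterior,
)

atlas = load_atlas("default")
cohort = generate_cohort(SimulationConfig(n=1500, seed=7), atlas)
design = build_design(cohort.volumes, cohort.phenotypes, "household", atlas=atlas)
print(f"design: n={design.n}, group sizes={design.group_counts().tolist()}")

draws = sample_posterior(
    design, PriorConfig(), SamplerConfig(n_draws=1500, burn_in=500, chains=2, seed=7)
)
summary = summarize_posterior(draws, atlas)

regions = summary[summary["parameter_type"] == "region"]
top = regions.reindex(regions["posterior_mean"].abs().sort_values(ascending=False).index).head(5)
print("\nstrongest region x group associations with z-scored age:")
for _, row in top.iterrows():
    print(
        f"  {row.region:10s} {row.group:26s} mean={row.posterior_mean:+.3f} "
        f"95% HPDI=({row.hpdi_lower:+.3f}, {row.hpdi_upper:+.3f})"
    )

diag = convergence_diagnostics(draws)
print(f"\nconvergence: max split R-hat = {diag['rhat'].max():.3f} "
      f"(should be ~1), min ESS = {diag['ess'].min():.0f}")
print("An HPDI excluding zero marks a region whose volume tracks age within")
print("that sex x household group; the hierarchy shrinks noisy regions toward")
print("their network-level coefficient.")
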