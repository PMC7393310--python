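"""Ground-truth recovery: can the model re-estimate known coefficients?

Generates a cohort whose z-age was constructed from known region x group
coefficients, fits the hierarchical model, and compares posterior means and
HPDIs against the generating truth — the core validity check for the whole
pipeline.
"""

from sbhbm import SamplerConfig, SimulationConfig
from sbhbm.synthetic_data import recovery_experiment

report = recovery_experiment(
    SimulationConfig(n=2000, seed=0),
    SamplerConfig(n_draws=1500, burn_in=500, chains=2, seed=0),
)

print(f"n = {report.n}, 144 region x group coefficients")
print(f"correlation(truth, posterior means) = {report.correlation:.3f}")
print(f"95% HPDI coverage of the truths     = {report.coverage:.3f}")
print(f"mean |hierarchical - network truth| = {report.shrinkage_hier:.4f}")
print(f"mean |least squares - network truth|= {report.shrinkage_ols:.4f}")
print("\nCorrelation near 1 and coverage near 0.95 mean the sampler finds the")
print("generating coefficients and its uncertainty intervals are calibrated;")
print("the smaller hierarchical distance shows partial pooling at work.")
print(report.table.head(8).to_string(index=False))
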