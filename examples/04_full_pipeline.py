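"""End-to-end run: simulate -> prepare -> fit -> report for all three indices.

Writes per-index posterior summary CSVs, convergence diagnostics, per-network
figures and a reproducibility manifest into ./pipeline_demo/.
"""

from pathlib import Path

from sbhbm.hier_model import SamplerConfig
from sbhbm.pipeline import PipelineConfig, run_pipeline
from sbhbm.synthetic_data import SimulationConfig

config = PipelineConfig(
    simulation=SimulationConfig(n=800, seed=1),
    sampler=SamplerConfig(n_draws=1200, burn_in=400, chains=2, seed=1),
    indices=("support", "household", "friendship"),
    make_figures=True,
)
out = run_pipeline(config, Path("pipeline_demo"))
print("pipeline outputs:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
print("\nEach summary_<index>.csv holds 144 region x group rows (plus network,")
print("confound and noise rows) with posterior means and 95% HPDIs; rerunning")
print("with the same config reproduces them byte for byte.")
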