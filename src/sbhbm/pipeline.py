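"""End-to-end driver: simulate -> (extract) -> prepare -> fit -> report.

One pipeline run fits the hierarchical model independently for each requested
social index on a shared synthetic cohort, writes per-index posterior summary
CSVs and diagnostics, per-network figures, and a run manifest (config hash,
seeds, file digests).  Re-running with the same configuration reproduces the
numeric outputs bit for bit; only the manifest timestamp differs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import NETWORKS, Atlas, load_atlas
from .cohort import GROUP_LABELS, SOCIAL_INDICES, DesignMatrix, build_design
from .hier_model import (
    PriorConfig,
    SamplerConfig,
    convergence_diagnostics,
    sample_posterior,
    summarize_posterior,
)
from .synthetic_data import SimulationConfig, SyntheticCohort, generate_cohort

__all__ = [
    "STAGE_EXIT_CODES",
    "PipelineError",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "render_network_report",
    "save_design",
    "load_design",
]

logger = logging.getLogger(__name__)

#: Exit code per failing stage family (0 = success).
STAGE_EXIT_CODES = {
    "config": 2,
    "simulate": 3,
    "extract": 4,
    "prepare": 5,
    "fit": 6,
    "report": 7,
}


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: study conditions, sampler protocol, indices."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    indices: tuple[str, ...] = SOCIAL_INDICES
    make_figures: bool = True

    def __post_init__(self) -> None:
        unknown = [i for i in self.indices if i not in SOCIAL_INDICES]
        if unknown:
            raise PipelineError(
                "config", f"unknown social index/indices {unknown}; expected subset of {SOCIAL_INDICES}"
            )
        if not self.indices:
            raise PipelineError("config", "at least one social index is required")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            sim = raw.get("simulation", {})
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            for key in ("support_probs", "household_probs", "friendship_probs"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            return cls(
                simulation=SimulationConfig(**sim),
                sampler=SamplerConfig(**raw.get("sampler", {})),
                priors=PriorConfig(**raw.get("priors", {})),
                indices=tuple(raw.get("indices", SOCIAL_INDICES)),
                make_figures=bool(raw.get("make_figures", True)),
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("config", f"cannot parse {path}: {exc}") from exc

    def to_dict(self) -> dict:
        d = {
            "simulation": asdict(self.simulation),
            "sampler": asdict(self.sampler),
            "priors": asdict(self.priors),
            "indices": list(self.indices),
            "make_figures": self.make_figures,
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one output directory."""

    config_hash: str
    seeds: dict
    file_digests: dict
    software_version: str
    timestamp: str

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_design(design: DesignMatrix, path: Union[str, Path]) -> None:
    """Persist a design as a compressed npz bundle."""
    np.savez_compressed(
        path,
        X=design.X, y=design.y, C=design.C, g=design.g,
        network_index=design.network_index,
        region_names=np.array(design.region_names),
        participant_ids=np.array(design.participant_ids),
        social_index=np.array(design.social_index),
        n_groups=np.array(design.n_groups),
    )


def load_design(path: Union[str, Path]) -> DesignMatrix:
    with np.load(path, allow_pickle=False) as z:
        return DesignMatrix(
            X=z["X"], y=z["y"], C=z["C"], g=z["g"],
            social_index=str(z["social_index"]),
            region_names=[str(s) for s in z["region_names"]],
            network_index=z["network_index"],
            participant_ids=[str(s) for s in z["participant_ids"]],
            n_groups=int(z["n_groups"]),
        )


def render_network_report(
    summary: pd.DataFrame,
    network: str,
    ax=None,
):
    """Per-network panel: posterior mean +/- HPDI per (region, group).

    Returns ``(figure, table_slice)``; the plotted numbers are taken directly
    from the summary table, never recomputed.
    """
    import matplotlib

    if matplotlib.get_backend().lower() not in ("agg",):  # headless-safe default
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if network not in set(summary["network"]):
        raise PipelineError("report", f"unknown network {network!r}")
    sl = summary[(summary["parameter_type"] == "region") & (summary["network"] == network)]
    sl = sl.reset_index(drop=True)
    if sl.empty:
        raise PipelineError("report", f"no region rows for network {network!r}")

    regions = list(dict.fromkeys(sl["region"]))
    groups = list(dict.fromkeys(sl["group"]))
    if ax is None:
        fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(regions) * len(groups) / 2), 4))
    else:
        fig = ax.figure
    width = 0.8 / len(groups)
    for k, grp in enumerate(groups):
        part = sl[sl["group"] == grp]
        xs = np.array([regions.index(r) for r in part["region"]]) + (k - (len(groups) - 1) / 2) * width
        means = part["posterior_mean"].to_numpy()
        err = np.vstack([
            means - part["hpdi_lower"].to_numpy(),
            part["hpdi_upper"].to_numpy() - means,
        ])
        ax.errorbar(xs, means, yerr=err, fmt="o", ms=3, capsize=2, label=grp)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xticks(range(len(regions)))
    ax.set_xticklabels(regions, rotation=45, ha="right")
    ax.set_ylabel("association with z-scored age\n(posterior mean, 95% HPDI)")
    ax.set_title(f"{network} network")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig, sl


def run_pipeline(
    config: Union[PipelineConfig, str, Path],
    out_dir: Union[str, Path],
    atlas: Optional[Atlas] = None,
) -> Path:
    """Run the full pipeline and populate ``out_dir``.

    Outputs: ``phenotypes.csv``, ``volumes.csv``, ``ground_truth.csv``, per
    index ``summary_<index>.csv`` + ``diagnostics_<index>.csv`` (+ figures),
    and ``manifest.json``.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = atlas if atlas is not None else load_atlas("default")
    written: list[Path] = []

    try:
        cohort = generate_cohort(config.simulation, atlas)
        pheno_path = out / "phenotypes.csv"
        cohort.phenotypes.to_csv(pheno_path, index=False)
        vol_path = out / "volumes.csv"
        cohort.volumes.to_csv(vol_path)
        gt_path = out / "ground_truth.csv"
        cohort.ground_truth.to_frame(atlas.names).to_csv(gt_path, index=False)
        written += [pheno_path, vol_path, gt_path]
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    seeds = {"simulation": config.simulation.seed}
    for i, index in enumerate(config.indices):
        try:
            design = build_design(cohort.volumes, cohort.phenotypes, index, atlas=atlas)
        except Exception as exc:
            raise PipelineError("prepare", f"index {index!r}: {exc}") from exc
        try:
            sampler = replace(config.sampler, seed=config.sampler.seed + i)
            seeds[f"fit_{index}"] = sampler.seed
            draws = sample_posterior(design, config.priors, sampler)
            summary = summarize_posterior(draws, atlas)
            spath = out / f"summary_{index}.csv"
            summary.to_csv(spath, index=False)
            written.append(spath)
            if sampler.chains >= 2:
                diag = convergence_diagnostics(draws)
                dpath = out / f"diagnostics_{index}.csv"
                diag.to_csv(dpath, index=False)
                written.append(dpath)
        except Exception as exc:
            raise PipelineError("fit", f"index {index!r}: {exc}") from exc
        if config.make_figures:
            try:
                present = sorted(set(summary.loc[summary["parameter_type"] == "region", "network"]))
                for network in present:
                    fig, _ = render_network_report(summary, network)
                    fig.savefig(out / f"report_{index}_{network}.png", dpi=120)
                    import matplotlib.pyplot as plt

                    plt.close(fig)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("report", f"index {index!r}: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.digest(),
        seeds=seeds,
        file_digests={p.name: _sha256(p) for p in written},
        software_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %s", out)
    return out
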