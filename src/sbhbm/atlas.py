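"""Social brain atlas: 36 regions grouped into four functional networks.

The atlas is a table of named gray-matter loci in MNI152 space, each assigned
to one of four networks spanning the processing hierarchy of social cognition:
``visual_sensory`` (6 regions), ``limbic`` (8), ``intermediate`` (11) and
``higher_associative`` (11).  Region ids 1..36 are laid out in contiguous
network blocks (1-6, 7-14, 15-25, 26-36).

The packaged default file ships *synthetic* MNI coordinates: plausible
locations for the named regions, spaced so that geometric fixtures built on
them never overlap.  They stand in for the published meta-analytic peak
coordinates, which are distributed separately; analyses of real images should
load a user-supplied atlas CSV with the transcribed coordinates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS",
    "NETWORK_BLOCKS",
    "AtlasRegion",
    "Atlas",
    "AtlasValidationError",
    "load_atlas",
    "network_of",
]

#: Canonical network labels, in region-id block order.
NETWORKS = ("visual_sensory", "limbic", "intermediate", "higher_associative")

#: region_id ranges (inclusive) of the default contiguous network blocks.
NETWORK_BLOCKS = {
    "visual_sensory": (1, 6),
    "limbic": (7, 14),
    "intermediate": (15, 25),
    "higher_associative": (26, 36),
}

_EXPECTED_BLOCK_SIZES = {
    "visual_sensory": 6,
    "limbic": 8,
    "intermediate": 11,
    "higher_associative": 11,
}

_HEMISPHERES = ("L", "R", "midline")

_REQUIRED_COLUMNS = ["region_id", "name", "hemisphere", "network", "x", "y", "z"]


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates the 36-region / 4-network contract."""


@dataclass(frozen=True)
class AtlasRegion:
    """One named social-brain locus."""

    region_id: int
    name: str
    hemisphere: str
    network: str
    center_mni: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise AtlasValidationError(
                f"region {self.region_id} ({self.name}): unknown network "
                f"{self.network!r}; expected one of {NETWORKS}"
            )
        if self.hemisphere not in _HEMISPHERES:
            raise AtlasValidationError(
                f"region {self.region_id} ({self.name}): unknown hemisphere "
                f"{self.hemisphere!r}; expected one of {_HEMISPHERES}"
            )


@dataclass(frozen=True)
class Atlas:
    """Ordered collection of 36 regions plus provenance."""

    regions: tuple[AtlasRegion, ...]
    source: str = "packaged-default"

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if sorted(ids) != list(range(1, len(self.regions) + 1)):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise AtlasValidationError(
                f"region_id values must be unique and cover 1..{len(self.regions)}; "
                f"got {sorted(ids)}" + (f" (duplicates: {sorted(dupes)})" if dupes else "")
            )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[AtlasRegion]:
        return iter(self.regions)

    def __getitem__(self, region_id: int) -> AtlasRegion:
        if not 1 <= region_id <= len(self.regions):
            raise KeyError(f"region_id {region_id} out of range 1..{len(self.regions)}")
        return self.regions[region_id - 1]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def centers(self) -> np.ndarray:
        """(n_regions, 3) array of MNI mm coordinates, region_id order."""
        return np.array([r.center_mni for r in self.regions], dtype=float)

    @property
    def network_labels(self) -> list[str]:
        return [r.network for r in self.regions]

    @property
    def network_index(self) -> np.ndarray:
        """Per region, the index of its network in :data:`NETWORKS`."""
        return np.array([NETWORKS.index(r.network) for r in self.regions])

    def network_sizes(self) -> dict[str, int]:
        sizes = {n: 0 for n in NETWORKS}
        for r in self.regions:
            sizes[r.network] += 1
        return sizes

    def regions_in_network(self, network: str) -> list[AtlasRegion]:
        if network not in NETWORKS:
            raise AtlasValidationError(f"unknown network {network!r}")
        return [r for r in self.regions if r.network == network]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": self.names,
                "hemisphere": [r.hemisphere for r in self.regions],
                "network": self.network_labels,
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
            }
        )


def _default_atlas_path() -> Path:
    return Path(
        importlib.resources.files("sbhbm").joinpath(
            "data/default_atlas_synthetic_coords.csv"
        )
    )


def load_atlas(path: Union[str, Path] = "default", *, strict: bool = True) -> Atlas:
    """Load and validate an atlas definition table.

    Parameters
    ----------
    path:
        CSV file with header ``region_id,name,hemisphere,network,x,y,z``,
        or the string ``"default"`` for the packaged 36-region atlas.
    strict:
        When true (default), require exactly 36 regions with network block
        sizes 6/8/11/11.  Non-strict mode accepts any consistent region set
        (useful for small geometric test atlases).

    Returns
    -------
    Atlas
        Regions ordered by ``region_id``.
    """
    if isinstance(path, str) and path == "default":
        file, source = _default_atlas_path(), "packaged-default"
    else:
        file, source = Path(path), str(path)
    df = pd.read_csv(file)

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasValidationError(f"atlas file {source}: missing column(s) {missing}")

    df = df.sort_values("region_id").reset_index(drop=True)
    regions = tuple(
        AtlasRegion(
            region_id=int(row.region_id),
            name=str(row.name),
            hemisphere=str(row.hemisphere),
            network=str(row.network),
            center_mni=(float(row.x), float(row.y), float(row.z)),
        )
        for row in df.itertuples(index=False)
    )
    atlas = Atlas(regions=regions, source=source)

    if strict:
        if len(atlas) != 36:
            raise AtlasValidationError(
                f"atlas file {source}: expected 36 regions, found {len(atlas)}"
            )
        sizes = atlas.network_sizes()
        if sizes != _EXPECTED_BLOCK_SIZES:
            raise AtlasValidationError(
                f"atlas file {source}: network partition {sizes} != "
                f"expected {_EXPECTED_BLOCK_SIZES}"
            )
    return atlas


def network_of(atlas: Atlas, region_id: int) -> str:
    """Network label of a region; raises ``KeyError`` on out-of-range ids."""
    return atlas[region_id].network
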