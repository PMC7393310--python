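import numpy as np
import pandas as pd
import pytest

from sbhbm.atlas import NETWORKS, load_atlas
from sbhbm.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_atlas():
    return load_atlas("default")


@pytest.fixture(scope="session")
def small_atlas(tmp_path_factory):
    """Four well-separated regions (one per network) for geometric fixtures."""
    rows = [
        dict(region_id=i + 1, name=f"R{i + 1}", hemisphere="midline", network=net,
             x=x, y=y, z=z)
        for i, ((x, y, z), net) in enumerate(
            zip([(-25, 0, 0), (25, 0, 0), (0, 25, 0), (0, -25, 0)], NETWORKS)
        )
    ]
    path = tmp_path_factory.mktemp("atlas") / "small_atlas.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return load_atlas(path, strict=False)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort under default study conditions."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimulationConfig(n=400, seed=11))


def write_atlas_csv(path, df):
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def atlas_frame(default_atlas):
    return default_atlas.to_frame()
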