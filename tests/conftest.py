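import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lowbiome import synthetic as syn


@pytest.fixture(scope="session")
def amplicon_dataset():
    return syn.simulate_asv_table(syn.AmpliconSimConfig(seed=7))


@pytest.fixture(scope="session")
def spatial_dataset():
    cfg = syn.SpatialSimConfig(seed=7, n_fovs=2, cells_per_fov=50, n_planted_positive_cells=15)
    return syn.simulate_transcript_cloud(cfg)


@pytest.fixture(scope="session")
def shotgun_dataset():
    return syn.simulate_read_hits(syn.ShotgunSimConfig(seed=7))


@pytest.fixture(scope="session")
def dsp_matrix():
    return syn.simulate_dsp_matrix(seed=7)
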