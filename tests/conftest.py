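import numpy as np
import pytest

from mgnet import simulate as sim
from mgnet.tables import FeatureTable, SampleMetadata


@pytest.fixture(scope="session")
def small_cfg():
    return sim.SimulationConfig(seed=101, n_genes=120, n_taxa=16,
                                n_cf=10, n_healthy=12, n_controls=2,
                                seq_depth_range=(5000, 9000),
                                nb_dispersion=0.2)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return sim.make_truth(small_cfg, n_de_genes=20, n_da_taxa=4,
                          n_contaminants=3, n_links=6,
                          basis_pairs=[(6, 7, 0.8)])


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_truth):
    return sim.simulate_dataset(small_cfg, small_truth)


@pytest.fixture
def toy_meta():
    return [
        SampleMetadata("A1", "CF", "CF_df508", False),
        SampleMetadata("A2", "CF", "CF_other", False),
        SampleMetadata("A3", "CF", "CF_df508", False),
        SampleMetadata("B1", "Healthy", "Healthy", False),
        SampleMetadata("B2", "Healthy", "Healthy", False),
        SampleMetadata("B3", "Healthy", "Healthy", False),
    ]


@pytest.fixture
def toy_table():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(8, 6)).astype(float)
    return FeatureTable(counts, "counts",
                        feature_ids=[f"F{i}" for i in range(8)],
                        sample_ids=["A1", "A2", "A3", "B1", "B2", "B3"])
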