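import pytest

import scpcnet as s


@pytest.fixture(scope="session")
def six_type_dataset():
    """Scaled-down default study design: 3 patients x {AC, PA}, six cell
    types with exclusive markers, 5% spiked cross-type doublets."""
    cfg = s.SimConfig(
        cells_per_sample={"AC": 450, "PA": 180}, n_genes=300, seed=5
    )
    adata, truth = s.generate_cells(cfg)
    return s.spike_doublets(adata, truth, rate=0.05)


@pytest.fixture(scope="session")
def six_type_partitioning(six_type_dataset):
    adata, _ = six_type_dataset
    return s.partition_cells(adata, seed=0)
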