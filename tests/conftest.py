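import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial simulated dataset shared across tests."""
    from tlabelbench.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_cells=12,
        n_genes=80,
        mean_umis_per_cell=250,
        p_c=0.08,
        background_pe=0.002,
        seed=11,
    )
    reads, truth = simulate_dataset(config)
    return config, reads, truth


@pytest.fixture(scope="session")
def small_summaries(small_dataset):
    from tlabelbench import quantify

    _, reads, _ = small_dataset
    return quantify.consensus_umis(reads)


def make_summaries_frame(k, n, gene_index, gene_ids, barcodes=None):
    """Wrap bare (k, n) UMI draws into the tabular summary form."""
    k = np.asarray(k)
    n = np.asarray(n)
    gene_index = np.asarray(gene_index)
    n_umis = len(k)
    if barcodes is None:
        barcodes = np.array([f"cell{i % 8:03d}" for i in range(n_umis)])
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "umi": [f"umi{i:07d}" for i in range(n_umis)],
            "gene_id": np.asarray(gene_ids)[gene_index],
            "A": 10,
            "C": 10,
            "G": 10,
            "T": n,
        }
    )
    from tlabelbench.quantify import SUB_TYPES

    for sub in SUB_TYPES:
        df[sub] = 0
    df["TC"] = k
    return df
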