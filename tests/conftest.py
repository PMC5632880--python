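import numpy as np
import pandas as pd
import pytest

from mitomir import CountTable, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast-but-realistic simulation: 60 miRNAs, 8 planted mitomiRs."""
    return SimulationConfig(
        n_mirnas=60,
        library_size_per_group=200_000,
        mitomir_indices=tuple(range(8)),
        seed=7,
    )


@pytest.fixture
def two_library_table() -> CountTable:
    """A minimal mitochondrial-fraction table with two identical libraries."""
    rng = np.random.default_rng(3)
    counts = rng.poisson(50, size=(10, 1))
    counts = np.hstack([counts, counts])
    meta = pd.DataFrame(
        {
            "library_id": ["mito_sham", "mito_tac4w"],
            "compartment": ["mitochondrial"] * 2,
            "condition": ["sham", "tac4w"],
            "library_size": [int(counts[:, 0].sum())] * 2,
        }
    )
    return CountTable(
        mirna_ids=[f"mmu-miR-t{i}" for i in range(10)],
        libraries=meta,
        counts=counts,
    )
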