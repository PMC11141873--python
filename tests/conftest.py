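import numpy as np
import pandas as pd
import pytest

from promoscreen.expression import CountMatrix
from promoscreen.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture
def small_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "s1": [10, 90, 0, 5],
            "s2": [20, 60, 0, 20],
            "s3": [5, 80, 0, 15],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    lengths = pd.Series([1000, 2000, 500, 1500], index=counts.index)
    return CountMatrix(counts=counts, gene_length_bp=lengths)


@pytest.fixture(scope="session")
def demo_dataset():
    """One small synthetic dataset shared across tests (read-only)."""
    cfg = SimulationConfig(
        n_genes=300, n_samples=60, n_targets=50, promoter_len_bp=1000, rng_seed=42
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
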