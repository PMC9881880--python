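import numpy as np
import pandas as pd
import pytest

from gnibench import SyntheticConfig, degrade_reference, generate_planted_dataset
from gnibench.evaluation import Universe


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """4 genes × 3 samples with easy arithmetic."""
    return pd.DataFrame(
        [[1, 10, 100], [3, 30, 300], [0, 0, 0], [6, 60, 600]],
        index=["A", "B", "C", "D"],
        columns=["s1", "s2", "s3"],
        dtype=float,
    )


@pytest.fixture(scope="session")
def planted():
    """Default synthetic study conditions: 200×100, 5 hubs × 10 targets, signal 0.9."""
    cfg = SyntheticConfig()
    counts, lengths, truth = generate_planted_dataset(cfg)
    return cfg, counts, lengths, truth


@pytest.fixture(scope="session")
def planted_complete_ref():
    """Planted dataset with a complete reference (coverage 1, no decoys)."""
    cfg = SyntheticConfig(reference_coverage=1.0, reference_noise_edges=0)
    counts, lengths, truth = generate_planted_dataset(cfg)
    ref = degrade_reference(truth, cfg)
    universe = Universe.from_genes(counts.index, ref)
    return cfg, counts, lengths, truth, ref, universe


def random_association(rng: np.random.Generator, n_genes: int) -> pd.DataFrame:
    """Symmetric random score matrix with zero diagonal (test helper)."""
    a = rng.uniform(size=(n_genes, n_genes))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(a, index=genes, columns=genes)
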