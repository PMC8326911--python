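import numpy as np
import pytest
from hypothesis import settings

from metaneutral import OtuTable

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 taxa x 2 samples with easy totals."""
    counts = np.array([[2, 0], [3, 1], [5, 4]])
    return OtuTable(counts, ("tA", "tB", "tC"), ("s1", "s2"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_table(
    rng: np.random.Generator, n_taxa: int = 30, n_samples: int = 6
) -> OtuTable:
    counts = rng.integers(0, 50, size=(n_taxa, n_samples))
    counts[rng.random(n_taxa) < 0.2] = 0  # some all-zero rows
    # make sure no sample column is empty
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1
    return OtuTable(
        counts,
        tuple(f"OTU_{i}" for i in range(n_taxa)),
        tuple(f"s{j}" for j in range(n_samples)),
    )
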