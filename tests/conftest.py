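import numpy as np
import pytest

from normrank.counts_io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_count_matrix(rng, n_genes=50, n_samples=4, low=1, high=400, groups=True):
    counts = rng.integers(low, high, size=(n_genes, n_samples))
    half = n_samples // 2
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        group_labels=(["A"] * half + ["B"] * (n_samples - half)) if groups else None,
    )


@pytest.fixture
def small_cm(rng):
    return random_count_matrix(rng)


@pytest.fixture
def identical_samples_cm(rng):
    col = rng.integers(1, 200, size=30)
    counts = np.tile(col[:, None], (1, 4))
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(30)],
        sample_ids=[f"s{j}" for j in range(4)],
        group_labels=["A", "A", "B", "B"],
    )
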