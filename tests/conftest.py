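import numpy as np
import pytest

from infonet import AdjacencyMatrix, DiscreteSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_series(rng, length, k=20, source_id="s"):
    return DiscreteSeries(
        values=rng.integers(1, k + 1, size=length), k=k, source_id=source_id
    )


def random_normalized_adjacency(rng, n, edge_prob=0.6):
    """Symmetric matrix with uniform(0,1] weights on a random edge set."""
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                values[i, j] = values[j, i] = rng.uniform(0.05, 1.0)
    return AdjacencyMatrix(
        values=values, ids=[f"n{i}" for i in range(n)], normalized=True
    )
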