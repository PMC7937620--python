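import numpy as np
import pytest

from netimage import DiseaseAnnotation, GeneNetwork


def random_network(rng, n, density=0.3, name="rand", weighted=True):
    """Random symmetric zero-diagonal network with continuous weights."""
    upper = np.triu(rng.uniform(0.1, 2.0, (n, n)), 1)
    mask = np.triu(rng.uniform(size=(n, n)) < density, 1)
    w = np.where(mask, upper, 0.0)
    if not weighted:
        w = (w > 0).astype(float)
    w = w + w.T
    return GeneNetwork(
        name=name,
        genes=[f"g{i}" for i in range(n)],
        weights=w,
        is_binary=not weighted,
    )


def dense_network(rng, n, name="dense"):
    """Fully weighted network; generic weights, so no similarity ties."""
    upper = np.triu(rng.uniform(0.1, 2.0, (n, n)), 1)
    w = upper + upper.T
    return GeneNetwork(name=name, genes=[f"g{i}" for i in range(n)], weights=w)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_cluster_network():
    """Genes 0,1 wired to gene 4; genes 2,3 wired to gene 5 (near-identical
    row pairs, well separated)."""
    n = 6
    w = np.zeros((n, n))
    w[0, 4] = w[4, 0] = 5.0
    w[1, 4] = w[4, 1] = 5.1
    w[2, 5] = w[5, 2] = 5.0
    w[3, 5] = w[5, 3] = 5.2
    w[4, 5] = w[5, 4] = 0.7
    return GeneNetwork("two_cluster", [f"g{i}" for i in range(n)], w)


@pytest.fixture
def small_annotation():
    return DiseaseAnnotation(
        tags={
            "g0": frozenset({1}),
            "g1": frozenset({1, 2}),
            "g2": frozenset({2}),
            "g3": frozenset({3}),
        },
        n_classes=3,
        target_class=1,
    )
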