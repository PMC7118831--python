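import numpy as np
import pytest

from waftest import GenotypeMatrix, TraitVector


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_binary():
    """n=6 balanced case/control with K=3 integer genotypes."""
    y = TraitVector(np.array([1, 1, 1, 0, 0, 0], dtype=float))
    g = GenotypeMatrix(
        np.array(
            [
                [2, 0, 1],
                [1, 1, 0],
                [2, 0, 0],
                [0, 1, 1],
                [0, 2, 0],
                [1, 0, 2],
            ],
            dtype=float,
        )
    )
    return y, g


@pytest.fixture
def toy_continuous():
    """n=6 continuous trait with dyadic values (exact float arithmetic)."""
    y = TraitVector(
        np.array([1, 2, 3, 4, 5, 6], dtype=float), trait_type="continuous"
    )
    g = GenotypeMatrix(
        np.array(
            [
                [0, 2, 1],
                [1, 0, 0],
                [2, 1, 0],
                [0, 0, 2],
                [1, 2, 0],
                [2, 1, 1],
            ],
            dtype=float,
        )
    )
    return y, g


def random_dataset(rng, n=40, k=5, trait_type="binary"):
    """Small random polymorphic dataset for identity/property checks."""
    while True:
        g = rng.integers(0, 3, size=(n, k)).astype(float)
        if (g.var(axis=0) > 0).all():
            break
    if trait_type == "binary":
        y = rng.integers(0, 2, size=n).astype(float)
        while y.var() == 0:
            y = rng.integers(0, 2, size=n).astype(float)
    else:
        y = rng.standard_normal(n)
    return TraitVector(y, trait_type=trait_type), GenotypeMatrix(g)
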