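import numpy as np
import pytest

from hexamyloid import EffectMatrix, default_matrix
from hexamyloid.fixtures import random_matrix


@pytest.fixture(scope="session")
def matrix() -> EffectMatrix:
    """The embedded default effect matrix."""
    return default_matrix()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221)


@pytest.fixture
def random_matrices():
    """Factory: n seeded random effect matrices (deterministic)."""

    def make(n: int, seed: int = 7) -> list[EffectMatrix]:
        gen = np.random.default_rng(seed)
        return [random_matrix(gen) for _ in range(n)]

    return make


@pytest.fixture
def zero_matrix():
    """All-zero entries; bias settable by the test."""

    def make(bias: int) -> EffectMatrix:
        return EffectMatrix(np.zeros((20, 6), dtype=int), bias)

    return make
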