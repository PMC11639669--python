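import numpy as np
import pytest

from pssmcompare import ALPHABET, PSSM, normalise


def one_hot(aa: str) -> np.ndarray:
    col = np.zeros(20)
    col[ALPHABET.index(aa)] = 1.0
    return col


@pytest.fixture
def proline_column() -> np.ndarray:
    return one_hot("P")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20241029)


@pytest.fixture
def random_normalised_pssm(rng) -> PSSM:
    return normalise(PSSM(name="rand", weights=rng.random((20, 6))))


def random_columns(rng, m: int) -> np.ndarray:
    """Normalised random columns (m, 20): each attains 0 and 1."""
    X = rng.random((m, 20))
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    return (X - lo) / (hi - lo)
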