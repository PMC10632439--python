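import numpy as np
import pytest

from splicescreen import GeometryParams, OccurrenceParams, ScoringParams


@pytest.fixture
def geometry():
    return GeometryParams()


@pytest.fixture
def scoring():
    return ScoringParams()


@pytest.fixture
def occurrence():
    return OccurrenceParams()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
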