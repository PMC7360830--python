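import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

_ALPHA = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHA[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def rand_seq(rng):
    def _make(n: int) -> str:
        return random_seq(rng, n)

    return _make


@pytest.fixture(scope="session")
def test_ancestor():
    """Session-scoped default synthetic plastome with planted structures."""
    from plastomics.simulate import build_ancestor, default_preset

    cfg = default_preset()
    plastome, truth = build_ancestor(cfg, 11)
    return cfg, plastome, truth
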