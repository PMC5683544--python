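import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from mitocmp import CircularGenome
from mitocmp.simulate import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    return CircularGenome("small", random_dna(2000, 0.45, rng))


@pytest.fixture
def insert_fixture(rng):
    """B = 10 kb random circle; A = B plus a 500 bp novel insert at 4 kb."""
    base = random_dna(10_000, 0.45, rng)
    insert = random_dna(500, 0.45, np.random.default_rng(4242))
    a = CircularGenome("A", base[:4000] + insert + base[4000:])
    b = CircularGenome("B", base)
    return a, b
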