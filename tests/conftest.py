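import random

import numpy as np
import pytest

from orgkit.genome import GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def random_dna(n: int, seed: int = 0) -> str:
    r = random.Random(seed)
    return "".join(r.choice("ACGT") for _ in range(n))


@pytest.fixture
def small_genome():
    return GenomeRecord(id="toy", sequence=random_dna(2000, seed=5))
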