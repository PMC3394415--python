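import numpy as np
import pytest

from medmix.genomes import Genome, apply_inversion


def random_genome(rng: np.random.Generator, n: int, name: str = "") -> Genome:
    perm = rng.permutation(np.arange(2, n + 1))
    signs = rng.choice([1, -1], size=n - 1)
    return Genome((1,) + tuple(int(s * g) for s, g in zip(signs, perm)), name)


def mutate(rng: np.random.Generator, g: Genome, k: int) -> Genome:
    for _ in range(k):
        i, j = sorted(int(rng.integers(1, g.n + 1)) for _ in range(2))
        g = apply_inversion(g, i, j)
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
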